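"""Stage 5: chemical-shift-based discrimination of structural models.

Two comparisons characterize a state from its chemical shifts alone:

* agreement with random-coil predictions (RMSD over selected atoms and a
  residue range) — a disordered region matches coil shifts closely;
* Spearman rank correlation between experimental shifts of a state and
  shifts predicted from candidate structure models — the model whose
  predictions correlate best is the likeliest structure for that state.

Predictor outputs arrive as plain delimited tables; a minimal NMR-STAR
reader covers experimental shift lists.  Matching is by (residue number,
atom name) after atom-name normalization (Greek letters to Roman, HN to H).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "normalize_atom",
    "read_shift_table",
    "read_nmrstar_shifts",
    "coil_rmsd",
    "model_correlation",
    "rank_models",
]

_ATOM_ALIASES = {
    "CA": "CA", "CÁ": "CA", "CΑ": "CA", "CALPHA": "CA",
    "CB": "CB", "CΒ": "CB", "CBETA": "CB",
    "CG": "CG", "CΓ": "CG", "CGAMMA": "CG",
    "CD": "CD", "CΔ": "CD", "CDELTA": "CD",
    "HN": "H", "H": "H", "HA": "HA",
    "N": "N", "NH": "N", "C": "C", "CO": "C",
}


def normalize_atom(name: str) -> str:
    """Canonical atom name: Cα/CALPHA -> CA, HN -> H, case-insensitive."""
    key = str(name).strip().upper().replace("Α", "A").replace("Β", "B")
    return _ATOM_ALIASES.get(key, key)


def read_shift_table(path) -> pd.DataFrame:
    """Read a delimited shift table (residue, residue_type, atom, shift_ppm,
    [source]); atom names are normalized on the way in."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = {"residue", "atom", "shift_ppm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"shift table {path} is missing column(s): {sorted(missing)}")
    df["atom"] = df["atom"].map(normalize_atom)
    df["residue"] = df["residue"].astype(int)
    return df


def read_nmrstar_shifts(path) -> pd.DataFrame:
    """Minimal NMR-STAR v3 chemical-shift reader.

    Parses the ``_Atom_chem_shift`` loop only (sequence id, residue type,
    atom id, shift value), which is all a shift comparison needs; full STAR
    parsing is out of scope.
    """
    cols = []
    rows = []
    in_loop = False
    reading = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line == "loop_":
                in_loop, cols, reading = True, [], False
                continue
            if in_loop and line.startswith("_"):
                cols.append(line.split(".", 1)[-1] if "." in line else line.lstrip("_"))
                continue
            if in_loop and cols:
                if line in ("stop_", ""):
                    if reading:
                        break
                    in_loop = False
                    continue
                if not any(c.startswith("Atom_chem_shift") or c in
                           ("Seq_ID", "Comp_ID", "Atom_ID", "Val") for c in cols):
                    in_loop = False
                    continue
                reading = True
                rows.append(line.split())
    if not rows:
        raise ValueError(f"{path}: no _Atom_chem_shift loop found")
    frame = pd.DataFrame(rows, columns=cols[: len(rows[0])])
    idx = {c.lower(): c for c in frame.columns}
    out = pd.DataFrame(
        {
            "residue": frame[idx["seq_id"]].astype(int),
            "residue_type": frame[idx["comp_id"]],
            "atom": frame[idx["atom_id"]].map(normalize_atom),
            "shift_ppm": frame[idx["val"]].astype(float),
        }
    )
    return out


def _match(a: pd.DataFrame, b: pd.DataFrame, residues=None, atoms=None):
    """Inner-join two shift tables on (residue, atom)."""
    left, right = a.copy(), b.copy()
    for df in (left, right):
        df["atom"] = df["atom"].map(normalize_atom)
    if residues is not None:
        residues = set(residues)
        left = left[left["residue"].isin(residues)]
        right = right[right["residue"].isin(residues)]
    if atoms is not None:
        atoms = {normalize_atom(x) for x in atoms}
        left = left[left["atom"].isin(atoms)]
        right = right[right["atom"].isin(atoms)]
    merged = left.merge(right, on=["residue", "atom"], suffixes=("_a", "_b"))
    return merged


def coil_rmsd(experimental: pd.DataFrame, coil: pd.DataFrame,
              residue_range=None, atoms=("N", "H", "CA", "CB")):
    """RMSD (ppm) between experimental and random-coil shifts.

    ``residue_range`` is an inclusive (first, last) pair in sequence
    numbering.  Returns ``(rmsd, n_pairs)``; zero matches raise with the
    offending selection named.
    """
    residues = None
    if residue_range is not None:
        residues = range(int(residue_range[0]), int(residue_range[1]) + 1)
    m = _match(experimental, coil, residues=residues, atoms=atoms)
    if m.empty:
        raise ValueError(
            f"no matched (residue, atom) pairs for range {residue_range} and atoms {atoms}"
        )
    diff = m["shift_ppm_a"] - m["shift_ppm_b"]
    return float(np.sqrt(np.mean(diff**2))), int(len(m))


@dataclass
class CorrelationResult:
    rho: float
    n: int
    defined: bool


def model_correlation(experimental: pd.DataFrame, predicted: pd.DataFrame,
                      residues=None, atoms=None) -> CorrelationResult:
    """Spearman rank correlation between experimental and predicted shifts.

    Ties are mid-ranked (scipy's convention).  A constant predicted vector
    has no rank ordering; the result is returned flagged undefined rather
    than raising.
    """
    m = _match(experimental, predicted, residues=residues, atoms=atoms)
    if len(m) < 3:
        raise ValueError(f"need >= 3 matched pairs, got {len(m)}")
    if m["shift_ppm_b"].nunique() == 1 or m["shift_ppm_a"].nunique() == 1:
        return CorrelationResult(rho=np.nan, n=len(m), defined=False)
    rho, _p = spearmanr(m["shift_ppm_a"], m["shift_ppm_b"])
    return CorrelationResult(rho=float(rho), n=int(len(m)), defined=True)


def rank_models(experimental_by_state: dict, predicted: dict,
                residues=None, atoms=None):
    """Correlation cross table and per-state verdicts.

    Parameters
    ----------
    experimental_by_state:
        ``{state: shift table}``.
    predicted:
        ``{(model, predictor): shift table}``.

    Returns ``(table, verdicts)``: a DataFrame with one row per
    (state, model, predictor) holding rho and pair count (absent
    combinations appear as NaN rows), and per state the argmax model for
    each predictor plus a majority verdict across predictors (``None`` on a
    tie, never a silent winner).
    """
    models = sorted({m for m, _p in predicted})
    predictors = sorted({p for _m, p in predicted})
    if len(models) < 2:
        raise ValueError("model ranking needs at least two candidate models")
    rows = []
    for state, exp in experimental_by_state.items():
        for model in models:
            for pred in predictors:
                key = (model, pred)
                if key not in predicted:
                    rows.append({"state": state, "model": model, "predictor": pred,
                                 "rho": np.nan, "n": 0})
                    continue
                c = model_correlation(exp, predicted[key], residues=residues, atoms=atoms)
                rows.append({"state": state, "model": model, "predictor": pred,
                             "rho": c.rho if c.defined else np.nan, "n": c.n})
    table = pd.DataFrame(rows)
    verdicts = {}
    for state in experimental_by_state:
        sub = table[table["state"] == state]
        winners = []
        per_predictor = {}
        for pred in predictors:
            cell = sub[sub["predictor"] == pred].dropna(subset=["rho"])
            if cell.empty:
                continue
            best_rho = cell["rho"].max()
            best = sorted(cell[cell["rho"] == best_rho]["model"])
            per_predictor[pred] = best[0] if len(best) == 1 else tuple(best)
            if len(best) == 1:
                winners.append(best[0])
        majority = None
        if winners:
            counts = pd.Series(winners).value_counts()
            if len(counts) == 1 or counts.iloc[0] > counts.iloc[1]:
                majority = counts.index[0]
        verdicts[state] = {"per_predictor": per_predictor, "majority": majority}
    return table, verdicts
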