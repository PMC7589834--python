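"""Consensus deleteriousness classification of missense variants.

Nine predictor tools are consumed as score columns (they are never
re-run here): SIFT, PolyPhen-2 (HumDiv and HumVar jointly, one tool),
PROVEAN, I-Mutant 3.0, PhD-SNP, SNP&GO, PANTHER, PredictSNP and MAPP.
Each tool has a published deleteriousness cutoff with the boundary
applied exactly as printed (SIFT <= 0.05 is inclusive, I-Mutant < -0.5
exclusive, ...).  Missing scores ('-' cells) are *no-calls*: they never
count toward nor against a variant, so a variant supported by seven
tools with two tools silent is still a seven-tool consensus hit.

A variant is consensus-deleterious when at least ``min_tools`` of the
nine tools call it deleterious (7 by default).  Pairwise tool agreement
is summarised with the phi coefficient of the binary calls over the
variants both tools called.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ScoreTableError

__all__ = [
    "TOOLS",
    "VariantRecord",
    "CutoffTable",
    "parse_substitution",
    "read_score_table",
    "load_packaged_table",
    "apply_cutoffs",
    "consensus",
    "tool_agreement_matrix",
]

#: The nine tools of the consensus (PolyPhen-2 counts once despite its
#: two sub-scores).
TOOLS = (
    "SIFT", "PolyPhen2", "MAPP", "PANTHER", "SNP_GO", "PhD_SNP",
    "PredictSNP", "PROVEAN", "I_Mutant3",
)

_AA = set("ACDEFGHIKLMNPQRSTVWY")

_SUB_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")

# column-header aliases accepted on input
_ALIASES = {
    "sift": "SIFT",
    "polyphen2_humdiv": "PolyPhen2_HumDiv",
    "polyphen 2 humdiv": "PolyPhen2_HumDiv",
    "humdiv": "PolyPhen2_HumDiv",
    "polyphen2_humvar": "PolyPhen2_HumVar",
    "polyphen 2 humvar": "PolyPhen2_HumVar",
    "humvar": "PolyPhen2_HumVar",
    "mapp": "MAPP",
    "panther": "PANTHER",
    "snp_go": "SNP_GO",
    "snp & go": "SNP_GO",
    "snp&go": "SNP_GO",
    "phd_snp": "PhD_SNP",
    "phd-snp": "PhD_SNP",
    "predictsnp": "PredictSNP",
    "provean": "PROVEAN",
    "i_mutant3": "I_Mutant3",
    "i-mutant 3": "I_Mutant3",
    "i-mutant 3.0": "I_Mutant3",
    "rs_id": "rs_id",
    "rs id": "rs_id",
    "rsid": "rs_id",
    "substitution": "substitution",
}

_SCORE_COLUMNS = (
    "SIFT", "PolyPhen2_HumDiv", "PolyPhen2_HumVar", "MAPP", "PANTHER",
    "SNP_GO", "PhD_SNP", "PredictSNP", "PROVEAN", "I_Mutant3",
)


def parse_substitution(text: str):
    """Parse ``G1050V`` into ``('G', 1050, 'V')`` with validation."""
    m = _SUB_RE.match(str(text).strip())
    if not m:
        raise ScoreTableError(f"malformed substitution {text!r}")
    wild, pos, mutant = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    for aa in (wild, mutant):
        if aa not in _AA:
            raise ScoreTableError(
                f"{text!r}: {aa!r} is not a one-letter amino-acid code"
            )
    if wild == mutant:
        raise ScoreTableError(f"{text!r}: wild-type equals mutant residue")
    if pos < 1:
        raise ScoreTableError(f"{text!r}: position must be >= 1")
    return wild, pos, mutant


@dataclass(frozen=True)
class VariantRecord:
    """One nsSNP: identity plus its per-tool scores (None = missing)."""

    rs_id: str
    substitution: str
    wild: str
    position: int
    mutant: str
    scores: dict

    @classmethod
    def from_row(cls, row: dict) -> "VariantRecord":
        wild, pos, mutant = parse_substitution(row["substitution"])
        scores = {c: row.get(c) for c in _SCORE_COLUMNS}
        return cls(str(row.get("rs_id", "")), str(row["substitution"]),
                   wild, pos, mutant, scores)


@dataclass
class CutoffTable:
    """Deleteriousness rule per tool, boundaries exactly as published.

    Categorical tools (PredictSNP, MAPP when given labels) accept 'D';
    their numeric fallback threshold is configurable.
    """

    sift_max: float = 0.05          # deleterious when score <= 0.05
    polyphen_min: float = 0.9       # both HumDiv and HumVar > 0.9
    provean_max: float = -2.5       # <= -2.5
    imutant_max: float = -0.5       # <  -0.5 (strict)
    phd_snp_min: float = 0.5        # >  0.5
    snp_go_min: float = 0.5         # >  0.5
    panther_min: float = 0.5        # >= 0.5
    predictsnp_min: float = 0.5     # 'D' or score > 0.5
    mapp_min: float = 0.5           # 'D' or score > 0.5


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    if isinstance(value, str) and value.strip() in ("", "-", "NA", "nan"):
        return True
    return False


def _numeric(value, tool: str, rs_id: str) -> float:
    if isinstance(value, str):
        try:
            value = float(value.replace("−", "-"))
        except ValueError:
            raise ScoreTableError(
                f"{rs_id}/{tool}: non-numeric score {value!r}"
            ) from None
    return float(value)


def _categorical_call(value, numeric_min: float, tool: str, rs_id: str) -> str:
    if isinstance(value, str) and value.strip().upper() in ("D", "N"):
        return "deleterious" if value.strip().upper() == "D" else "neutral"
    score = _numeric(value, tool, rs_id)
    return "deleterious" if score > numeric_min else "neutral"


def apply_cutoffs(record: VariantRecord,
                  cutoffs: CutoffTable | None = None) -> dict:
    """Per-tool call in {'deleterious', 'neutral', 'no_call'}."""
    cutoffs = cutoffs or CutoffTable()
    s = record.scores
    rs = record.rs_id
    calls = {}

    def numeric_rule(tool, column, passes):
        if _is_missing(s.get(column)):
            return "no_call"
        return "deleterious" if passes(_numeric(s[column], tool, rs)) else "neutral"

    calls["SIFT"] = numeric_rule("SIFT", "SIFT", lambda x: x <= cutoffs.sift_max)
    # PolyPhen-2: one tool, both sub-models must pass; either missing -> no_call
    hd, hv = s.get("PolyPhen2_HumDiv"), s.get("PolyPhen2_HumVar")
    if _is_missing(hd) or _is_missing(hv):
        calls["PolyPhen2"] = "no_call"
    else:
        both = (
            _numeric(hd, "PolyPhen2_HumDiv", rs) > cutoffs.polyphen_min
            and _numeric(hv, "PolyPhen2_HumVar", rs) > cutoffs.polyphen_min
        )
        calls["PolyPhen2"] = "deleterious" if both else "neutral"
    calls["PROVEAN"] = numeric_rule(
        "PROVEAN", "PROVEAN", lambda x: x <= cutoffs.provean_max)
    calls["I_Mutant3"] = numeric_rule(
        "I_Mutant3", "I_Mutant3", lambda x: x < cutoffs.imutant_max)
    calls["PhD_SNP"] = numeric_rule(
        "PhD_SNP", "PhD_SNP", lambda x: x > cutoffs.phd_snp_min)
    calls["SNP_GO"] = numeric_rule(
        "SNP_GO", "SNP_GO", lambda x: x > cutoffs.snp_go_min)
    calls["PANTHER"] = numeric_rule(
        "PANTHER", "PANTHER", lambda x: x >= cutoffs.panther_min)
    for tool, thr in (("PredictSNP", cutoffs.predictsnp_min),
                      ("MAPP", cutoffs.mapp_min)):
        if _is_missing(s.get(tool)):
            calls[tool] = "no_call"
        else:
            calls[tool] = _categorical_call(s[tool], thr, tool, rs)
    return calls


def _normalise_columns(df: pd.DataFrame) -> pd.DataFrame:
    mapping = {}
    for col in df.columns:
        key = str(col).strip().lower().replace("&", "&").replace("  ", " ")
        mapping[col] = _ALIASES.get(key, str(col).strip())
    out = df.rename(columns=mapping)
    missing = [c for c in ("substitution",) if c not in out.columns]
    if missing:
        raise ScoreTableError(f"score table lacks column(s) {missing}")
    return out


def read_score_table(source) -> list[VariantRecord]:
    """Read a CSV/TSV score table (or DataFrame) into variant records.

    ``-`` and empty cells are missing values; a Unicode minus sign is
    accepted in numeric cells.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=None, engine="python", dtype=str)
    df = _normalise_columns(df)
    records = []
    for _, row in df.iterrows():
        d = {}
        for col, val in row.items():
            if _is_missing(val):
                d[col] = None
            elif isinstance(val, str):
                d[col] = val.strip().replace("−", "-")
            else:
                d[col] = val
        records.append(VariantRecord.from_row(d))
    if not records:
        raise ScoreTableError("score table is empty")
    return records


def load_packaged_table() -> pd.DataFrame:
    """The packaged ABCA1 most-deleterious-variant score table."""
    with resources.files("vardyn.data").joinpath(
        "abca1_table1.csv"
    ).open() as fh:
        return pd.read_csv(fh, dtype=str)


def consensus(
    records,
    cutoffs: CutoffTable | None = None,
    min_tools: int = 7,
) -> pd.DataFrame:
    """Consensus table sorted by tool support (descending), then rs_id.

    Columns: rs_id, substitution, one call per tool, ``n_deleterious``
    and ``is_consensus_deleterious`` (>= ``min_tools`` supporting
    tools).  No-calls never count toward ``n_deleterious``.
    """
    rows = []
    for rec in records:
        calls = apply_cutoffs(rec, cutoffs)
        n_del = sum(1 for c in calls.values() if c == "deleterious")
        row = {"rs_id": rec.rs_id, "substitution": rec.substitution}
        row.update(calls)
        row["n_deleterious"] = n_del
        row["is_consensus_deleterious"] = n_del >= min_tools
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["n_deleterious", "rs_id"], ascending=[False, True]
    ).reset_index(drop=True)


def tool_agreement_matrix(records, cutoffs: CutoffTable | None = None):
    """Pairwise phi coefficient of binary deleterious calls.

    For each tool pair the coefficient is computed over the variants
    where both tools made a call; pairs with no co-called variants, or
    where a tool's calls are constant, are undefined (NaN) and flagged.
    Returns ``(matrix, undefined_mask)`` as DataFrames.
    """
    if len(records) < 2:
        raise ScoreTableError("agreement needs at least 2 variants")
    calls = [apply_cutoffs(rec, cutoffs) for rec in records]
    binary = pd.DataFrame(
        [
            {t: (1.0 if c[t] == "deleterious"
                 else 0.0 if c[t] == "neutral" else np.nan)
             for t in TOOLS}
            for c in calls
        ]
    )
    n = len(TOOLS)
    phi = np.full((n, n), np.nan)
    undefined = np.zeros((n, n), dtype=bool)
    for i, ti in enumerate(TOOLS):
        for j, tj in enumerate(TOOLS):
            if i == j:
                phi[i, j] = 1.0
                continue
            both = binary[[ti, tj]].dropna()
            if len(both) == 0:
                undefined[i, j] = True
                continue
            a, b = both[ti].to_numpy(), both[tj].to_numpy()
            if a.std() == 0 or b.std() == 0:
                undefined[i, j] = True
                continue
            phi[i, j] = float(np.corrcoef(a, b)[0, 1])
    idx = pd.Index(TOOLS)
    return (pd.DataFrame(phi, index=idx, columns=idx),
            pd.DataFrame(undefined, index=idx, columns=idx))
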