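"""Proximity-labeling (TurboID) candidate-interactor filtering.

Protein-group evidence from bait (TF-biotin-ligase fusion) and negative
control samples is reduced to the candidate set exclusively and reproducibly
detected with the bait: present in the required number of bait replicates
and absent from every control replicate. Presence is a boolean supplied by
upstream identification; raw peptide/spectral counts can be binarized with a
minimum-count threshold.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .errors import DataError

__all__ = [
    "read_evidence",
    "filter_exclusive_candidates",
    "FilterSummary",
]

_REP_COL = re.compile(r"^(?P<condition>.+)_(?P<rep>\d+)$")
FIXED_COLUMNS = ("group_id", "member_proteins", "peptide_ids")


def read_evidence(path) -> pd.DataFrame:
    """Read a protein-group evidence TSV.

    Fixed columns ``group_id``, ``member_proteins`` and ``peptide_ids``
    (semicolon-separated lists), followed by one presence/count column per
    ``<condition>_<replicate>`` sample, e.g. ``bait_1 .. bait_3,
    control_1 .. control_3``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"group_id": str})
    missing = [c for c in FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    if not all(_REP_COL.match(c) for c in df.columns if c not in FIXED_COLUMNS):
        bad = [c for c in df.columns
               if c not in FIXED_COLUMNS and not _REP_COL.match(c)]
        raise DataError(f"{path}: unrecognized sample columns {bad}")
    return df


def sample_columns(df: pd.DataFrame) -> dict:
    """condition -> ordered list of its replicate columns."""
    out = {}
    for c in df.columns:
        if c in FIXED_COLUMNS:
            continue
        cond = _REP_COL.match(c).group("condition")
        out.setdefault(cond, []).append(c)
    return out


@dataclass(frozen=True)
class FilterSummary:
    n_groups: int
    n_peptides: int
    n_unique_proteins: int


def _split(cell):
    if pd.isna(cell) or cell == "":
        return []
    return str(cell).split(";")


def filter_exclusive_candidates(
    evidence: pd.DataFrame,
    bait="bait",
    control="control",
    n_bait_reps_required=None,
    allow_any_control=False,
    min_count=1,
    mode="group",
):
    """Retain groups exclusively present in the bait samples.

    A group is retained iff it is present (value >= ``min_count``) in at
    least ``n_bait_reps_required`` bait replicates (default: all of them)
    AND absent from every control replicate (unless
    ``allow_any_control=True``, which drops the control constraint).

    ``mode='peptide'`` applies the same rule per evidence row on tables with
    one row per peptide and keeps the groups having >=1 passing peptide;
    ``mode='group'`` (default) treats each row as one protein group.

    Returns ``(retained_df, FilterSummary)``; the summary deduplicates
    member proteins and peptide ids across retained rows.
    """
    cols = sample_columns(evidence)
    for cond in (bait, control):
        if cond not in cols or not cols[cond]:
            raise DataError(f"no replicate columns for condition {cond!r}")
    bait_cols, ctrl_cols = cols[bait], cols[control]
    need = len(bait_cols) if n_bait_reps_required is None else int(n_bait_reps_required)
    if not 1 <= need <= len(bait_cols):
        raise DataError(
            f"n_bait_reps_required={need} outside 1..{len(bait_cols)}"
        )

    present_bait = (evidence[bait_cols].fillna(0).astype(float) >= min_count)
    present_ctrl = (evidence[ctrl_cols].fillna(0).astype(float) >= min_count)
    keep = present_bait.sum(axis=1) >= need
    if not allow_any_control:
        keep &= ~present_ctrl.any(axis=1)

    if mode == "peptide":
        ok_groups = set(evidence.loc[keep, "group_id"])
        retained = evidence[keep].copy()
        retained_groups = ok_groups
    elif mode == "group":
        retained = evidence[keep].copy()
        retained_groups = set(retained["group_id"])
    else:
        raise DataError(f"unknown mode: {mode!r}")

    peptides, proteins = set(), set()
    for _, row in retained.iterrows():
        peptides.update(_split(row["peptide_ids"]))
        proteins.update(_split(row["member_proteins"]))
    summary = FilterSummary(
        n_groups=len(retained_groups),
        n_peptides=len(peptides),
        n_unique_proteins=len(proteins),
    )
    return retained.reset_index(drop=True), summary
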