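"""Integration of differential expression with promoter binding.

A gene knocked down in the RNAi lines is a *direct* target when a
reproducible binding site sits in its promoter window, an *indirect* target
when it is differentially expressed without promoter binding. Classification
is reported per validation level (VL1-VL3); nested peak sets make the direct
sets nest too.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .errors import ConfigError, DataError
from .peaks import LEVELS, LEVEL_RANK

__all__ = [
    "read_deg_table",
    "write_deg_table",
    "select_consistent_degs",
    "TargetCall",
    "classify_direct_indirect",
    "collapse_to_homoeologs",
    "ClassificationSummary",
    "summarize_classification",
]

DEG_COLUMNS = ["gene_id", "line", "stage", "log2fc", "fdr"]


def read_deg_table(path) -> pd.DataFrame:
    """Read a per-contrast differential-expression TSV.

    Expected columns: ``gene_id, line, stage, log2fc, fdr`` — one row per
    gene x RNAi line x ripening stage contrast. Missing contrasts are
    permitted; duplicated contrasts and non-numeric statistics are errors.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in DEG_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    for col in ("log2fc", "fdr"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            # +2 -> 1-based line number past the header
            raise DataError(f"{path}: non-numeric {col} at line {bad[0] + 2}")
        df[col] = converted
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise DataError(f"{path}: fdr outside [0, 1]")
    dup = df.duplicated(subset=["gene_id", "line", "stage"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise DataError(
            f"{path}: duplicate contrast ({row.gene_id}, {row.line}, {row.stage})"
        )
    return df[DEG_COLUMNS]


def write_deg_table(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def select_consistent_degs(
    deg,
    min_abs_log2fc=1.0,
    max_fdr=0.05,
    require_both_lines=True,
    stage_rule="any_stage",
):
    """Select genes consistently differentially expressed across RNAi lines.

    A contrast *qualifies* when ``|log2fc| >= min_abs_log2fc`` and
    ``fdr <= max_fdr`` (both inclusive, as the thresholds are stated). Under
    ``stage_rule='any_stage'`` a line passes when any of its stages
    qualifies; under ``'both_stages'`` every stage observed for that line
    must qualify. A gene is selected when every line passes
    (``require_both_lines=True``) or at least one does.

    Returns a DataFrame indexed by gene_id with a ``direction`` column:
    ``down`` if every qualifying contrast has negative log2fc, ``up`` if all
    positive, else ``mixed``.
    """
    if stage_rule not in ("any_stage", "both_stages"):
        raise ConfigError(f"unknown stage_rule: {stage_rule!r}")
    if deg is None or len(deg) == 0:
        raise DataError("empty differential-expression table")
    df = deg.copy()
    df["qual"] = (df["log2fc"].abs() >= min_abs_log2fc) & (df["fdr"] <= max_fdr)

    rows = []
    for gene, gdf in df.groupby("gene_id", sort=True):
        line_pass = []
        for _line, ldf in gdf.groupby("line", sort=True):
            if stage_rule == "any_stage":
                line_pass.append(bool(ldf["qual"].any()))
            else:
                line_pass.append(bool(ldf["qual"].all()) and len(ldf) > 0)
        selected = all(line_pass) if require_both_lines else any(line_pass)
        if not selected or not line_pass:
            continue
        signs = set(
            "down" if fc < 0 else "up" for fc in gdf.loc[gdf["qual"], "log2fc"]
        )
        direction = signs.pop() if len(signs) == 1 else "mixed"
        rows.append((gene, direction))
    return pd.DataFrame(rows, columns=["gene_id", "direction"]).set_index("gene_id")


@dataclass(frozen=True)
class TargetCall:
    """Joint ChIP/DEG classification of one gene."""

    gene_id: str
    deg_status: str  # selected | not_selected
    bound_at: str | None  # highest level with a promoter peak, or None
    direction: str  # up | down | mixed | NA
    homoeolog_group: str | None = None

    @property
    def cls(self) -> str:
        if self.deg_status == "selected":
            return "direct" if self.bound_at else "indirect"
        return "bound_not_DE" if self.bound_at else "neither"

    def direct_at(self, level) -> bool:
        """Direct under the cumulative reading of ``level``."""
        return (
            self.deg_status == "selected"
            and self.bound_at is not None
            and LEVEL_RANK[self.bound_at] >= LEVEL_RANK[level]
        )


def classify_direct_indirect(selected, target_maps, universe=None):
    """Combine selected DEGs with per-level promoter binding.

    Parameters
    ----------
    selected
        DataFrame from :func:`select_consistent_degs` (index gene_id,
        ``direction`` column) or mapping gene_id -> direction.
    target_maps
        ``{level: {gene_id: [peaks]}}`` from
        :func:`~polytarget.annotate.assign_target_genes`, evaluated on the
        cumulative peak set of each level.
    universe
        Optional iterable of all annotated gene ids, so that unbound,
        unselected genes appear as ``neither``. Defaults to the union of
        selected and bound genes.
    """
    if hasattr(selected, "index") and hasattr(selected, "loc"):
        directions = selected["direction"].to_dict()
    else:
        directions = dict(selected)
    bound_levels = {}
    for level, tmap in target_maps.items():
        if level not in LEVEL_RANK:
            raise ConfigError(f"unknown validation level: {level!r}")
        for gene in tmap:
            prev = bound_levels.get(gene)
            if prev is None or LEVEL_RANK[level] > LEVEL_RANK[prev]:
                bound_levels[gene] = level
    if universe is None:
        universe = set(directions) | set(bound_levels)
    calls = []
    for gene in sorted(universe):
        sel = gene in directions
        calls.append(
            TargetCall(
                gene_id=gene,
                deg_status="selected" if sel else "not_selected",
                bound_at=bound_levels.get(gene),
                direction=directions.get(gene, "NA"),
            )
        )
    return calls


def attach_homoeolog_groups(calls, hmap):
    return [
        TargetCall(
            gene_id=c.gene_id,
            deg_status=c.deg_status,
            bound_at=c.bound_at,
            direction=c.direction,
            homoeolog_group=hmap.get(c.gene_id),
        )
        for c in calls
    ]


def collapse_to_homoeologs(calls, hmap):
    """Count distinct homoeolog groups per class and level.

    Returns a dict with, per level, unique-group counts for direct calls,
    plus level-independent counts for indirect and the unmapped tally. The
    octoploid gene counts stay available from the calls themselves; this
    view answers "how many distinct ancestral genes" each class touches.
    """
    out = {"unmapped_genes": 0}
    unmapped = set()
    for level in LEVELS:
        groups = set()
        for c in calls:
            if c.direct_at(level):
                g = hmap.get(c.gene_id)
                if g is None:
                    unmapped.add(c.gene_id)
                else:
                    groups.add(g)
        out[f"direct_{level}"] = len(groups)
    for cls in ("indirect", "bound_not_DE"):
        groups = set()
        for c in calls:
            if c.cls == cls:
                g = hmap.get(c.gene_id)
                if g is None:
                    unmapped.add(c.gene_id)
                else:
                    groups.add(g)
        out[cls] = len(groups)
    out["unmapped_genes"] = len(unmapped)
    return out


def round1(x):
    """Round half-up to one decimal, as percentages are reported."""
    if x is None:
        return None
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ClassificationSummary:
    """Counts and percentages of the direct/indirect partition, per level."""

    n_selected_degs: int
    n_direct: dict
    n_indirect: dict
    n_down: dict
    n_up: dict
    n_mixed: dict
    pct_direct: dict
    pct_indirect: dict
    pct_down: dict
    pct_up: dict
    n_bound_not_de: dict

    def to_dict(self):
        return {
            "n_selected_degs": self.n_selected_degs,
            **{f"n_direct_{l}": self.n_direct[l] for l in LEVELS},
            **{f"n_indirect_{l}": self.n_indirect[l] for l in LEVELS},
            **{f"n_down_{l}": self.n_down[l] for l in LEVELS},
            **{f"n_up_{l}": self.n_up[l] for l in LEVELS},
            **{f"n_mixed_{l}": self.n_mixed[l] for l in LEVELS},
            **{f"pct_direct_{l}": self.pct_direct[l] for l in LEVELS},
            **{f"pct_indirect_{l}": self.pct_indirect[l] for l in LEVELS},
            **{f"pct_down_{l}": self.pct_down[l] for l in LEVELS},
            **{f"pct_up_{l}": self.pct_up[l] for l in LEVELS},
            **{f"n_bound_not_DE_{l}": self.n_bound_not_de[l] for l in LEVELS},
        }


def summarize_classification(calls) -> ClassificationSummary:
    """Aggregate target calls into the per-level classification summary.

    ``pct_direct``/``pct_indirect`` are percentages of the selected DEGs;
    ``pct_down``/``pct_up`` are percentages of the direct targets with a
    consistent direction (the ``mixed`` bucket is excluded from that
    denominator and reported separately). With zero selected DEGs all
    percentages are ``None`` (NA), never 0.
    """
    n_selected = sum(1 for c in calls if c.deg_status == "selected")
    n_direct, n_indirect, n_down, n_up, n_mixed = {}, {}, {}, {}, {}
    pct_direct, pct_indirect, pct_down, pct_up = {}, {}, {}, {}
    n_bound_not_de = {}
    for level in LEVELS:
        direct = [c for c in calls if c.direct_at(level)]
        n_direct[level] = len(direct)
        n_indirect[level] = n_selected - len(direct)
        n_down[level] = sum(1 for c in direct if c.direction == "down")
        n_up[level] = sum(1 for c in direct if c.direction == "up")
        n_mixed[level] = sum(1 for c in direct if c.direction == "mixed")
        n_bound_not_de[level] = sum(
            1
            for c in calls
            if c.deg_status == "not_selected"
            and c.bound_at is not None
            and LEVEL_RANK[c.bound_at] >= LEVEL_RANK[level]
        )
        if n_selected > 0:
            pct_direct[level] = round1(100.0 * n_direct[level] / n_selected)
            pct_indirect[level] = round1(100.0 * n_indirect[level] / n_selected)
        else:
            pct_direct[level] = None
            pct_indirect[level] = None
        directional = n_down[level] + n_up[level]
        if directional > 0:
            pct_down[level] = round1(100.0 * n_down[level] / directional)
            pct_up[level] = round1(100.0 * n_up[level] / directional)
        else:
            pct_down[level] = None
            pct_up[level] = None
    return ClassificationSummary(
        n_selected_degs=n_selected,
        n_direct=n_direct,
        n_indirect=n_indirect,
        n_down=n_down,
        n_up=n_up,
        n_mixed=n_mixed,
        pct_direct=pct_direct,
        pct_indirect=pct_indirect,
        pct_down=pct_down,
        pct_up=pct_up,
        n_bound_not_de=n_bound_not_de,
    )
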