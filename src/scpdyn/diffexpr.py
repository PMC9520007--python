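"""Differential gene (DEG) and protein (DEP) calling.

Gene calls use FPKM-like abundances with a pseudocount-stabilized fold
change, log2((treated + 1) / (control + 1)), combined with a
Benjamini-Hochberg adjusted p-value filter.  Protein calls use iTRAQ-style
tables: within each mass-spec run, sample values are first divided by the
mean of that run's untreated reference samples, then treated and vehicle
groups are compared with an equal-variance two-sided t-test on log2 scale.
All cutoffs are inclusive (>= fold change, <= alpha).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

Direction = Literal["up", "down"]

DEFAULT_DEG_FC = math.log2(1.5)
RELAXED_DEG_FC = math.log2(1.3)
DEFAULT_DEP_FC = math.log2(1.1)


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene at one time point: treated/control abundance plus adjusted p."""

    gene: str
    time_point: float
    abundance_treated: float
    abundance_control: float
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        for v in (self.abundance_treated, self.abundance_control):
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{self.gene}: abundances must be finite and >= 0, got {v}")
        if self.adjusted_p is not None and not (0 <= self.adjusted_p <= 1):
            raise ValueError(f"{self.gene}: adjusted_p outside [0, 1]")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein in one run: sample values keyed by label, with roles."""

    protein_id: str
    peptide_count: int
    run_id: str
    sample_values: Mapping[str, float]
    sample_roles: Mapping[str, str]  # label -> treated | vehicle | untreated

    def __post_init__(self) -> None:
        if self.peptide_count < 1:
            raise ValueError(f"{self.protein_id}: peptide_count must be >= 1")
        for label, value in self.sample_values.items():
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{self.protein_id}/{label}: sample values must be positive")
            if label not in self.sample_roles:
                raise ValueError(f"{self.protein_id}: no role for sample {label!r}")

    def values_with_role(self, role: str) -> list[float]:
        return [v for label, v in self.sample_values.items() if self.sample_roles[label] == role]


@dataclass(frozen=True)
class DifferentialCall:
    """A feature passing the significance and fold-change filters."""

    feature: str
    time_point: float
    log2_fold_change: float
    direction: Direction
    significance: float

    def __post_init__(self) -> None:
        expected = "up" if self.log2_fold_change >= 0 else "down"
        if self.direction != expected:
            raise ValueError(
                f"{self.feature}: direction {self.direction!r} inconsistent with "
                f"log2fc {self.log2_fold_change:+.3f}"
            )


def log2fc_pseudocount(treated: float, control: float) -> float:
    """log2((treated + 1) / (control + 1)); the +1 tames low-abundance noise."""
    if treated < 0 or control < 0:
        raise ValueError("abundances must be non-negative")
    return math.log2((treated + 1.0) / (control + 1.0))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])


def _to_call(feature: str, time_point: float, lfc: float, significance: float) -> DifferentialCall:
    return DifferentialCall(
        feature=feature,
        time_point=time_point,
        log2_fold_change=lfc,
        direction="up" if lfc >= 0 else "down",
        significance=significance,
    )


def call_degs(
    records: Iterable[ExpressionRecord],
    fdr_alpha: float = 0.05,
    min_abs_log2fc: float = DEFAULT_DEG_FC,
) -> list[DifferentialCall]:
    """Call DEGs: adjusted p <= ``fdr_alpha`` and |log2fc| >= ``min_abs_log2fc``.

    Records are grouped by time point; output order is (time, gene) so the
    result is invariant to input order.
    """
    if min_abs_log2fc < 0:
        raise ValueError("min_abs_log2fc must be >= 0")
    calls = []
    for rec in records:
        if rec.adjusted_p is None:
            raise ValueError(f"{rec.gene}: adjusted_p missing; apply bh_adjust upstream")
        lfc = log2fc_pseudocount(rec.abundance_treated, rec.abundance_control)
        if rec.adjusted_p <= fdr_alpha and abs(lfc) >= min_abs_log2fc:
            calls.append(_to_call(rec.gene, rec.time_point, lfc, rec.adjusted_p))
    calls.sort(key=lambda c: (c.time_point, c.feature))
    return calls


def union_over_time(calls: Iterable[DifferentialCall]) -> frozenset[str]:
    """Features differentially expressed at >= 1 time point."""
    return frozenset(c.feature for c in calls)


def group_calls(
    calls: Iterable[DifferentialCall],
) -> dict[tuple[float, Direction], frozenset[str]]:
    """Index call features by (time point, direction) for enrichment input."""
    grouped: dict[tuple[float, Direction], set[str]] = {}
    for c in calls:
        grouped.setdefault((c.time_point, c.direction), set()).add(c.feature)
    return {k: frozenset(v) for k, v in grouped.items()}


def normalize_proteomics_run(records: Iterable[ProteinRecord]) -> list[ProteinRecord]:
    """Divide each treated/vehicle value by the protein's mean untreated value of its run.

    Untreated values themselves pass through unchanged.  Proteins without an
    untreated reference in a run, or with a zero reference mean, are flagged
    and excluded from the output.
    """
    out: list[ProteinRecord] = []
    for rec in records:
        untreated = rec.values_with_role("untreated")
        if not untreated:
            logger.warning("%s (run %s): no untreated reference; excluded", rec.protein_id, rec.run_id)
            continue
        ref = float(np.mean(untreated))
        if ref <= 0:
            logger.warning("%s (run %s): zero untreated mean; excluded", rec.protein_id, rec.run_id)
            continue
        values = {
            label: (v / ref if rec.sample_roles[label] != "untreated" else v)
            for label, v in rec.sample_values.items()
        }
        out.append(replace(rec, sample_values=values))
    return out


def call_deps(
    records: Iterable[ProteinRecord],
    alpha: float = 0.05,
    min_abs_log2fc: float = DEFAULT_DEP_FC,
    min_peptides: int = 2,
    time_point: float = float("nan"),
    pool_runs: bool = True,
) -> list[DifferentialCall]:
    """Call DEPs from (already normalized) protein records.

    Proteins identified by fewer than ``min_peptides`` peptides are dropped
    first.  Treated and vehicle replicates are compared by a two-sample
    equal-variance two-sided t-test on log2 values; the fold change is the
    difference of group means on log2 scale.  A call requires nominal
    p <= ``alpha`` and |log2fc| >= ``min_abs_log2fc``.

    With ``pool_runs`` (default) replicates of the same protein are pooled
    across runs; otherwise each run is tested separately and a protein is
    called if any run passes.
    """
    by_key: dict[str, dict[str, list[float]]] = {}
    for rec in records:
        if rec.peptide_count < min_peptides:
            continue
        key = rec.protein_id if pool_runs else f"{rec.protein_id}\t{rec.run_id}"
        groups = by_key.setdefault(key, {"treated": [], "vehicle": []})
        groups["treated"].extend(rec.values_with_role("treated"))
        groups["vehicle"].extend(rec.values_with_role("vehicle"))

    calls = []
    for key in sorted(by_key):
        treated, vehicle = by_key[key]["treated"], by_key[key]["vehicle"]
        protein = key.split("\t")[0]
        if len(treated) < 2 or len(vehicle) < 2:
            logger.warning("%s: fewer than 2 replicates per group; skipped", protein)
            continue
        lt, lv = np.log2(treated), np.log2(vehicle)
        lfc = float(lt.mean() - lv.mean())
        p = float(stats.ttest_ind(lt, lv, equal_var=True).pvalue)
        if math.isnan(p):  # zero variance in both groups with equal means
            continue
        if p <= alpha and abs(lfc) >= min_abs_log2fc:
            calls.append(_to_call(protein, time_point, lfc, p))
    return calls


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def read_expression_table(source: str | Path) -> list[ExpressionRecord]:
    """Read a TSV with columns gene, time_h, fpkm_treated, fpkm_control, p_adj."""
    df = pd.read_csv(source, sep="\t")
    required = {"gene", "time_h", "fpkm_treated", "fpkm_control", "p_adj"}
    if missing := required - set(df.columns):
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    return [
        ExpressionRecord(
            gene=str(r.gene).upper(),
            time_point=float(r.time_h),
            abundance_treated=float(r.fpkm_treated),
            abundance_control=float(r.fpkm_control),
            adjusted_p=float(r.p_adj),
        )
        for r in df.itertuples(index=False)
    ]


def read_proteomics_table(source: str | Path) -> list[ProteinRecord]:
    """Read a long TSV with columns protein, peptides, run, sample, role, value."""
    df = pd.read_csv(source, sep="\t")
    required = {"protein", "peptides", "run", "sample", "role", "value"}
    if missing := required - set(df.columns):
        raise ValueError(f"proteomics table missing columns: {sorted(missing)}")
    records = []
    for (protein, run), grp in df.groupby(["protein", "run"], sort=True):
        records.append(
            ProteinRecord(
                protein_id=str(protein).upper(),
                peptide_count=int(grp["peptides"].iloc[0]),
                run_id=str(run),
                sample_values={str(r.sample): float(r.value) for r in grp.itertuples(index=False)},
                sample_roles={str(r.sample): str(r.role) for r in grp.itertuples(index=False)},
            )
        )
    return records


def calls_to_frame(calls: Iterable[DifferentialCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": c.feature,
                "time_point": c.time_point,
                "log2_fold_change": c.log2_fold_change,
                "direction": c.direction,
                "significance": c.significance,
            }
            for c in calls
        ]
    )
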