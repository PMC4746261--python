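"""Census and correlation reporting over TF inventories and regulons.

Ships a reference distribution table of carbohydrate-catabolism TFs across
ten *Bifidobacterium* genomes (eight families; for the TetR, AraC and GntR
families both the sugar-associated count and, in the ``*_all`` columns, the
family-wide total are kept, following the source table's footnote
convention — per-genome totals count only the sugar-associated values).
The last column is the percentage of carbohydrate-utilization genes (CUG%)
per genome, against which the TF totals are correlated.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .regulon_builder import Regulon
from .tf_catalog import Census, census_from_counts

#: family columns entering per-genome totals (sugar-associated counts)
FAMILY_COLUMNS = [
    "LacI", "ROK", "RpiR", "DeoR/SorC", "BglG", "TetR", "AraC", "GntR",
]


def load_reference_census() -> pd.DataFrame:
    """The packaged reference TF distribution table, indexed by genome."""
    with resources.files("regulonkit.data").joinpath(
        "bifidobacterium_tf_census.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="genome")
    return df


def reference_census() -> Census:
    """Census statistics recomputed from the packaged reference table."""
    return census_from_counts(load_reference_census()[FAMILY_COLUMNS])


@dataclass(frozen=True)
class GenomeSummaryRow:
    """Per-genome TF counts plus carbohydrate-utilization-gene percentage."""

    genome_id: str
    counts: dict[str, int]
    total: int
    cug_percent: float


def reference_rows() -> list[GenomeSummaryRow]:
    df = load_reference_census()
    rows = []
    for genome, row in df.iterrows():
        counts = {c: int(row[c]) for c in FAMILY_COLUMNS}
        rows.append(
            GenomeSummaryRow(
                genome_id=str(genome),
                counts=counts,
                total=int(sum(counts.values())),
                cug_percent=float(row["CUG_pct"]),
            )
        )
    return rows


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    r_squared: float
    r_squared_2dp: float
    n: int
    degenerate: bool  # fewer than 3 points: correlation is forced


def tf_vs_cug_correlation(rows: list[GenomeSummaryRow]) -> CorrelationResult:
    """Pearson correlation of total TF count vs CUG% across genomes.

    With only two rows the fit is exact by construction; the result is
    returned but flagged degenerate.  Constant columns are rejected.
    """
    if len(rows) < 2:
        raise ValueError("correlation needs at least 2 genomes")
    x = np.array([r.total for r in rows], dtype=float)
    y = np.array([r.cug_percent for r in rows], dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant column")
    if len(rows) == 2:
        r = 1.0 if (x[1] - x[0]) * (y[1] - y[0]) > 0 else -1.0
    else:
        r = float(stats.pearsonr(x, y).statistic)
    r2 = r * r
    return CorrelationResult(
        pearson_r=r,
        r_squared=r2,
        r_squared_2dp=round(r2, 2),
        n=len(rows),
        degenerate=len(rows) < 3,
    )


@dataclass
class CohortReport:
    totals: dict[str, int]
    presence: pd.DataFrame  # groups x genomes, '+' multiplicity notation


def summarize_cohort(
    regulons: list[Regulon], census: Census | None = None
) -> CohortReport:
    """Presence/absence matrix of TF groups across genomes ('+' per
    paralog) plus cohort totals consistent with the assembled regulons."""
    genome_ids = sorted(
        {m.genome_id for r in regulons for m in r.group.members}
    )
    data = {}
    for r in regulons:
        per_genome = {g: 0 for g in genome_ids}
        for m in r.group.members:
            per_genome[m.genome_id] += 1
        data[r.group.group_id] = {
            g: "+" * per_genome[g] for g in genome_ids
        }
    presence = pd.DataFrame.from_dict(data, orient="index")
    if len(presence):
        presence = presence.reindex(columns=genome_ids)
    totals = {
        "tfs": sum(r.n_tfs for r in regulons if r.members),
        "tfbs": sum(r.n_sites for r in regulons),
        "operons": sum(r.n_operons for r in regulons),
        "genes": sum(r.n_genes for r in regulons),
    }
    if census is not None:
        totals["tf_inventory"] = census.grand_total
    return CohortReport(totals=totals, presence=presence)


def report_markdown(report: CohortReport) -> str:
    lines = ["# Regulon cohort report", "", "## Totals", ""]
    for key in ("tfs", "tfbs", "operons", "genes"):
        lines.append(f"- {key}: {report.totals.get(key, 0)}")
    lines += ["", "## Group presence across genomes", ""]
    if len(report.presence):
        lines.append(report.presence.to_markdown())
    else:
        lines.append("(no reconstructed regulons)")
    return "\n".join(lines) + "\n"
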