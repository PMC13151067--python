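"""Selection analytics over peptide count tables.

The central container is the *pool table*, a tidy DataFrame with columns
``strategy, round, peptide, count`` — one row per peptide per sequenced
sample.  On top of it this module computes rank-abundance/diversity
profiles, round-over-round enrichment ratios, exclusive Venn regions with
read-weighted pool fractions, abundance scatter pairings, and the
consensus hit ranking that identifies strategy-independent binders while
flagging resin parasites.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "validate_pool_table",
    "sample_counts_series",
    "diversity_profile",
    "top_k_fraction",
    "enrichment_ratio",
    "RegionReport",
    "OverlapReport",
    "venn_regions",
    "abundance_scatter",
    "consensus_hits",
    "read_pool_table",
    "write_pool_table",
]

POOL_COLUMNS = ["strategy", "round", "peptide", "count"]


def validate_pool_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the pool-table contract: required columns, positive integer
    counts, no duplicate (strategy, round, peptide) rows."""
    missing = [c for c in POOL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"pool table missing columns: {missing}")
    if len(table) and (table["count"] <= 0).any():
        raise ValueError("counts must be positive integers")
    if table.duplicated(subset=["strategy", "round", "peptide"]).any():
        raise ValueError("duplicate (strategy, round, peptide) rows")
    return table


def _sample(table: pd.DataFrame, strategy: str, rnd: int) -> pd.DataFrame:
    sub = table[(table["strategy"] == strategy) & (table["round"] == rnd)]
    if sub.empty:
        raise ValueError(f"no reads for sample ({strategy!r}, round {rnd})")
    return sub


def sample_counts_series(table: pd.DataFrame, strategy: str, rnd: int) -> pd.Series:
    """Peptide→count for one sample."""
    sub = _sample(table, strategy, rnd)
    return sub.set_index("peptide")["count"]


def diversity_profile(table: pd.DataFrame, strategy: str, rnd: int) -> pd.DataFrame:
    """Rank-abundance curve for one sample.

    Peptides are sorted by descending count with lexicographic tie-break;
    the returned frame has ``rank`` (1-based), ``count``, ``frequency`` and
    ``cumulative_fraction`` columns, so the top-k cumulative fraction is
    row k of the last column.
    """
    sub = _sample(table, strategy, rnd).copy()
    sub = sub.sort_values(["count", "peptide"], ascending=[False, True]).reset_index(
        drop=True
    )
    total = sub["count"].sum()
    sub["rank"] = np.arange(1, len(sub) + 1)
    sub["frequency"] = sub["count"] / total
    sub["cumulative_fraction"] = sub["frequency"].cumsum()
    return sub[["rank", "peptide", "count", "frequency", "cumulative_fraction"]]


def top_k_fraction(table: pd.DataFrame, strategy: str, rnd: int, k: int) -> float:
    """Fraction of a sample's reads carried by its k most abundant peptides."""
    profile = diversity_profile(table, strategy, rnd)
    k = min(k, len(profile))
    return float(profile["cumulative_fraction"].iloc[k - 1])


def enrichment_ratio(
    table: pd.DataFrame, peptide: str, strategy: str, rnd: int
) -> float:
    """Round-over-round frequency ratio with a Jeffreys-style pseudo-count.

    ``(f_r + p) / (f_{r-1} + p)`` with ``p = 0.5 / total_{r-1}`` keeps the
    ratio finite when a peptide first appears in round r.
    """
    prev = sample_counts_series(table, strategy, rnd - 1)
    curr = sample_counts_series(table, strategy, rnd)
    total_prev = prev.sum()
    total_curr = curr.sum()
    p = 0.5 / total_prev
    f_prev = prev.get(peptide, 0) / total_prev
    f_curr = curr.get(peptide, 0) / total_curr
    return float((f_curr + p) / (f_prev + p))


@dataclass(frozen=True)
class RegionReport:
    """One exclusive Venn region: which sets it belongs to, its members,
    and its read-weighted share of the pooled samples."""

    members_of: frozenset[str]
    peptides: frozenset[str]
    size: int
    abundance_fraction: float


@dataclass(frozen=True)
class OverlapReport:
    sets: tuple[str, ...]
    regions: tuple[RegionReport, ...]
    union_size: int

    def region(self, *names: str) -> RegionReport:
        key = frozenset(names)
        for r in self.regions:
            if r.members_of == key:
                return r
        raise KeyError(f"no region for {sorted(key)}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                "&".join(sorted(r.members_of)),
                r.size,
                r.abundance_fraction,
            )
            for r in self.regions
        ]
        return pd.DataFrame(rows, columns=["region", "size", "abundance_fraction"])


def venn_regions(
    peptide_sets: dict[str, set[str]],
    table: pd.DataFrame | None = None,
    samples: dict[str, tuple[str, int]] | None = None,
    weighting: str = "reads",
) -> OverlapReport:
    """Exclusive-region decomposition of 2 or 3 peptide sets.

    With a pool table and a ``name → (strategy, round)`` mapping, each
    region also gets its share of the pooled sequencing reads: the region
    peptides' counts summed over the contributing samples, divided by the
    total reads of all samples (``weighting="reads"``, the default).
    ``weighting="unique"`` reports region size over union size instead.
    """
    names = tuple(peptide_sets)
    if len(names) not in (2, 3):
        raise ValueError("venn_regions needs 2 or 3 sets")
    if any(not s for s in peptide_sets.values()):
        raise ValueError("sets must be nonempty")
    if weighting not in ("reads", "unique"):
        raise ValueError(f"unknown weighting {weighting!r}")

    union = set().union(*peptide_sets.values())
    counts: dict[str, pd.Series] = {}
    grand_total = 0
    if table is not None:
        if samples is None:
            raise ValueError("samples mapping required when a table is given")
        for name in names:
            counts[name] = sample_counts_series(table, *samples[name])
            grand_total += int(counts[name].sum())

    regions = []
    for k in range(len(names), 0, -1):
        for members in combinations(names, k):
            inside = set.intersection(*(peptide_sets[n] for n in members))
            outside = set().union(
                *(peptide_sets[n] for n in names if n not in members), set()
            )
            exclusive = inside - outside
            fraction = np.nan
            if table is not None:
                region_reads = sum(
                    int(counts[n][counts[n].index.isin(exclusive)].sum())
                    for n in members
                )
                fraction = region_reads / grand_total if grand_total else 0.0
            elif weighting == "unique":
                fraction = len(exclusive) / len(union)
            if weighting == "unique":
                fraction = len(exclusive) / len(union)
            regions.append(
                RegionReport(
                    members_of=frozenset(members),
                    peptides=frozenset(exclusive),
                    size=len(exclusive),
                    abundance_fraction=float(fraction),
                )
            )
    report = OverlapReport(sets=names, regions=tuple(regions), union_size=len(union))
    assert sum(r.size for r in report.regions) == report.union_size
    return report


def abundance_scatter(
    table: pd.DataFrame,
    sample_x: tuple[str, int],
    sample_y: tuple[str, int],
) -> pd.DataFrame:
    """Paired frequencies over the union of two samples' peptides.

    A peptide absent from one sample gets frequency 0 there; the ``region``
    column labels each point ``both``, ``x-only`` or ``y-only`` to match
    the Venn coloring.
    """
    cx = sample_counts_series(table, *sample_x)
    cy = sample_counts_series(table, *sample_y)
    fx = cx / cx.sum()
    fy = cy / cy.sum()
    union = fx.index.union(fy.index)
    out = pd.DataFrame(
        {
            "peptide": union,
            "freq_x": fx.reindex(union, fill_value=0.0).values,
            "freq_y": fy.reindex(union, fill_value=0.0).values,
        }
    )
    out["region"] = np.select(
        [(out.freq_x > 0) & (out.freq_y > 0), out.freq_x > 0],
        ["both", "x-only"],
        default="y-only",
    )
    return out.sort_values("peptide").reset_index(drop=True)


def consensus_hits(
    table: pd.DataFrame,
    strategies: list[str],
    final_rounds: dict[str, int] | int,
    threshold: float = 1e-3,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Rank candidate hits by their worst per-strategy abundance rank.

    Candidates are peptides whose final-round frequency exceeds
    ``threshold`` (default 0.1%) in at least one strategy.  Within each
    strategy, candidates are competition-ranked ("1224") by frequency.
    A candidate above threshold in every strategy gets consensus rank =
    max over its per-strategy ranks; one below threshold somewhere is
    flagged ``strategy_restricted`` (resin-parasite suspicion) and sorts
    after all consensus-ranked peptides.  Ties break by descending mean
    frequency, then peptide string.
    """
    if len(strategies) < 2:
        raise ValueError("consensus ranking needs at least 2 strategies")
    if isinstance(final_rounds, int):
        final_rounds = {s: final_rounds for s in strategies}

    freqs: dict[str, pd.Series] = {}
    for s in strategies:
        counts = sample_counts_series(table, s, final_rounds[s])
        freqs[s] = counts / counts.sum()

    candidates = set()
    for s in strategies:
        candidates |= set(freqs[s][freqs[s] > threshold].index)
    if not candidates:
        return pd.DataFrame(
            columns=["peptide", "consensus_rank", "strategy_restricted", "mean_frequency"]
        )

    cand = sorted(candidates)
    data: dict[str, np.ndarray] = {}
    for s in strategies:
        f = freqs[s].reindex(cand, fill_value=0.0)
        # competition ranking among candidates, most abundant = 1
        data[f"freq_{s}"] = f.values
        data[f"rank_{s}"] = f.rank(method="min", ascending=False).astype(int).values

    out = pd.DataFrame({"peptide": cand, **data})
    above_all = np.ones(len(out), dtype=bool)
    for s in strategies:
        above_all &= out[f"freq_{s}"].values > threshold
    out["strategy_restricted"] = ~above_all
    rank_cols = [f"rank_{s}" for s in strategies]
    out["consensus_rank"] = out[rank_cols].max(axis=1)
    out["mean_frequency"] = out[[f"freq_{s}" for s in strategies]].mean(axis=1)

    out = out.sort_values(
        ["strategy_restricted", "consensus_rank", "mean_frequency", "peptide"],
        ascending=[True, True, False, True],
    ).reset_index(drop=True)
    if top_n is not None:
        out = out.head(top_n)
    return out


def read_pool_table(path) -> pd.DataFrame:
    """Read a pool table TSV (comment lines starting with # are ignored)."""
    table = pd.read_csv(path, sep="\t", comment="#")
    return validate_pool_table(table)


def write_pool_table(table: pd.DataFrame, path, header_comments: list[str] | None = None) -> None:
    validate_pool_table(table)
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False)
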