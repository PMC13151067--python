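"""Selection analytics: diversity, cross-strategy overlap, consensus hits.

A peptide enriched by genuine target binding rises in every parallel
strategy; a resin parasite rises only where its resin is used, so the
consensus ranking flags it strategy-restricted.
"""

import numpy as np

from macropan import consensus_hits, default_config, run_campaign, top_k_fraction, venn_regions
from macropan.simulate import RoundSpec

config = default_config(seed=42, n_clones=2000)
for rounds in config.campaigns.values():
    for i, spec in enumerate(rounds):
        rounds[i] = RoundSpec(**{**spec.__dict__, "depth": 20_000})
result = run_campaign(config, emit="counts")
table = result.pool_table()
truth = result.manifest.set_index("peptide")
strategies = sorted(config.campaigns)

for s in strategies:
    frac = top_k_fraction(table, s, 4, 4)
    print(f"{s}: top-4 peptides carry {frac:.1%} of round-4 reads")

sets = {s: set(table[(table.strategy == s) & (table["round"] == 4)].peptide)
        for s in strategies}
report = venn_regions(sets, table, {s: (s, 4) for s in strategies})
common = report.region(*strategies)
print(f"\ncommon to all three strategies: {common.size} peptides, "
      f"{common.abundance_fraction:.1%} of the pooled reads")

hits = consensus_hits(table, strategies, 4)
print("\nconsensus ranking (worst per-strategy abundance rank):")
for row in hits.head(7).itertuples():
    kind = ("binder" if np.isfinite(truth.loc[row.peptide].kd_molar)
            else "non-binder")
    flag = "  [strategy-restricted]" if row.strategy_restricted else ""
    print(f"  rank {row.consensus_rank:>2}  {row.peptide}  ({kind}){flag}")
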