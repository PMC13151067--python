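"""Generative model of multi-round phage-display biopanning.

Each selection round is modelled clone-wise on frequency scale:

* target occupancy        ``theta_i = T_r / (T_r + KD_i)`` with ``T_r`` the
  immobilized-target amount mapped to concentration units,
* negative selection      pass factor ``(1 - sigma)^k_neg`` against unloaded
  beads of the round's resin,
* capture probability     ``c_i = 1 - (1-theta)(1-sigma)(1-c0)``,
* per-wash retention      ``q_i = q_ns + (1-q_ns) * max(theta, sigma)``,
  applied ``W_r`` times,
* eluted weight           ``e_i = a_i * pass_i * c_i * q_i^{W_r}``,
* amplification           ``a'_i ∝ e_i * g_i * exp(eta_i)``,
  ``eta ~ Normal(0, tau)``.

``sigma`` is resin-specific stickiness — the parasite axis the alternating-
resin selection designs are built to defeat — and ``g`` is growth fitness.
Sequencing draws multinomial counts at the requested depth and emits reads
``flank5 + variable region + flank3`` with i.i.d. substitution errors.

All randomness flows from a single seeded ``numpy`` generator.  Stream
order: naive DNA per position, abundances, binder indices, binder KDs,
background stickiness per resin, parasite assignments, fitness; then per
round amplification noise; then per sequencing call multinomial counts and
error positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schema import (
    LibrarySchema,
    SequenceRejected,
    camcbt_12mer_schema,
    format_tokens,
    translate_with_suppression,
)

__all__ = [
    "RESINS",
    "ClonePool",
    "RoundSpec",
    "SimConfig",
    "CampaignResult",
    "EmptyElutionError",
    "default_config",
    "generate_naive_library",
    "run_round",
    "sample_counts",
    "reads_from_counts",
    "sequence_pool",
    "run_campaign",
    "write_fastq",
]

RESINS = ("streptavidin", "NHS", "GSH")


class EmptyElutionError(RuntimeError):
    """Every clone washed away — the round specification is over-stringent."""


@dataclass
class ClonePool:
    """Latent state of a phage pool: genotype plus selection-relevant traits.

    ``stickiness`` is an (n_clones, len(RESINS)) array of per-resin sigma
    values in [0, 1); ``kd`` is molar, ``np.inf`` for non-binders.
    """

    dna: np.ndarray            # object array of variable-region DNA strings
    peptides: np.ndarray       # object array of serialized token strings
    abundance: np.ndarray      # float, sums to 1
    kd: np.ndarray             # molar; inf = non-binder
    stickiness: np.ndarray     # (n, n_resins) in [0, 1)
    fitness: np.ndarray        # growth fitness g > 0

    def __post_init__(self) -> None:
        n = len(self.dna)
        for name in ("peptides", "abundance", "kd", "fitness"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != {n}")
        if self.stickiness.shape != (n, len(RESINS)):
            raise ValueError(f"stickiness must be (n, {len(RESINS)})")
        if np.any(self.abundance < 0):
            raise ValueError("abundances must be nonnegative")
        if abs(self.abundance.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")
        if np.any(self.stickiness >= 1) or np.any(self.stickiness < 0):
            raise ValueError("stickiness must lie in [0, 1)")
        if np.any(self.fitness <= 0):
            raise ValueError("fitness must be positive")

    def __len__(self) -> int:
        return len(self.dna)

    @property
    def is_binder(self) -> np.ndarray:
        return np.isfinite(self.kd)

    def with_abundance(self, abundance: np.ndarray) -> "ClonePool":
        return replace(self, abundance=abundance)


@dataclass(frozen=True)
class RoundSpec:
    """One selection round of one strategy."""

    strategy: str
    round_index: int
    resin: str
    target_ug: float           # immobilized target amount (μg)
    washes: int
    negative_selection: bool
    depth: int                 # sequencing depth (reads) if sequenced
    i5: str
    i7: str

    def __post_init__(self) -> None:
        if self.resin not in RESINS:
            raise ValueError(f"unknown resin {self.resin!r}")
        if self.target_ug < 0 or self.washes < 0 or self.depth <= 0:
            raise ValueError("target_ug >= 0, washes >= 0, depth > 0 required")


@dataclass
class SimConfig:
    """Simulator configuration; defaults mirror the alternating-resin
    12-mer campaign (four rounds, 10/5/2/1 μg target, 8→10 washes,
    three parallel strategies)."""

    schema: LibrarySchema = field(default_factory=camcbt_12mer_schema)
    n_clones: int = 10_000
    n_binders: int = 5
    binder_kd_range: tuple[float, float] = (50e-9, 5e-6)   # molar
    sticky_prevalence: float = 0.02
    sticky_beta: tuple[float, float] = (2.0, 5.0)
    n_parasites: int = 3
    parasite_sigma_range: tuple[float, float] = (0.9, 0.97)
    abundance_sigma: float = 1.0       # log-normal spread of naive abundances
    fitness_sigma: float = 0.1         # log-normal spread of growth fitness
    amp_noise_tau: float = 0.2         # amplification noise SD (log scale)
    c0: float = 0.01                   # baseline capture probability
    q_ns: float = 0.9                  # per-wash retention floor
    k_neg: float = 0.2                 # negative-selection strength (<1: bead
                                       # capacity saturates, depletion sub-linear)
    error_rate: float = 1e-3           # per-base substitution rate
    target_scale: float = 1e-5         # molar per μg: avidity-corrected
                                       # effective concentration of displayed target
    quality_char: str = "I"            # constant Phred+33 quality (Q40)
    seed: int = 0
    campaigns: dict[str, list[RoundSpec]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("sticky_prevalence", "c0", "q_ns", "error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.campaigns:
            self.campaigns = _default_campaigns()

    def final_round(self, strategy: str) -> int:
        return max(r.round_index for r in self.campaigns[strategy])


def _default_campaigns(depth: int = 100_000) -> dict[str, list[RoundSpec]]:
    """Three parallel four-round strategies with alternating resins, the
    stringency schedule 10/5/2/1 μg and 8/8/10/10 washes, and a unique
    (i5, i7) index pair per sample."""
    resin_plans = {
        "strep_nhs": ["streptavidin", "NHS", "streptavidin", "NHS"],
        "gsh": ["GSH", "GSH", "GSH", "GSH"],
        "gsh_nhs": ["GSH", "NHS", "GSH", "NHS"],
    }
    i5_pool = ["AGCGTAGC", "CCTGAGAT", "GTAAGGAG", "ACTGCATA"]
    i7_pool = ["TCGCCTTA", "CTAGTACG", "TTCTGCCT", "GCTCAGGA"]
    target_ug = [10.0, 5.0, 2.0, 1.0]
    washes = [8, 8, 10, 10]
    campaigns: dict[str, list[RoundSpec]] = {}
    for s_idx, (strategy, resins) in enumerate(resin_plans.items()):
        rounds = []
        for r in range(4):
            rounds.append(
                RoundSpec(
                    strategy=strategy,
                    round_index=r + 1,
                    resin=resins[r],
                    target_ug=target_ug[r],
                    washes=washes[r],
                    negative_selection=True,
                    depth=depth,
                    i5=i5_pool[s_idx],
                    i7=i7_pool[r],
                )
            )
        campaigns[strategy] = rounds
    return campaigns


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The default simulated campaign: 10^4 clones, 5 planted binders with
    KD in 50 nM – 5 μM, three alternating-resin strategies, depth 10^5."""
    return SimConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# naive library


def generate_naive_library(config: SimConfig, rng: np.random.Generator | None = None) -> ClonePool:
    """Draw a naive clone pool from the schema's codon schemes.

    DNA is drawn per position; clones whose translation fails (e.g. an
    unsuppressed in-frame amber in an NNK position) are discarded and
    redrawn until ``n_clones`` scaffold-valid clones exist.  Abundances are
    log-normal, heavy-tailed as in a real transformant library.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    schema = config.schema
    choices = [np.array(schema.codon_choices(p)) for p in schema.positions]

    dna_list: list[str] = []
    pep_list: list[str] = []
    guard = 0
    while len(dna_list) < config.n_clones:
        need = config.n_clones - len(dna_list)
        draw = max(need + 16, int(need * 1.6))
        cols = [c[rng.integers(0, len(c), size=draw)] for c in choices]
        for parts in zip(*cols):
            dna = "".join(parts)
            try:
                tokens = translate_with_suppression(dna, schema.code, schema.suppression)
            except SequenceRejected:
                continue
            if not schema.matches_scaffold(tokens):
                continue
            dna_list.append(dna)
            pep_list.append(format_tokens(tokens))
            if len(dna_list) == config.n_clones:
                break
        guard += 1
        if guard > 1000:
            raise ValueError("schema yields no valid clones")
    if not dna_list:
        raise ValueError("zero surviving clones")

    n = config.n_clones
    abundance = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    abundance /= abundance.sum()

    kd = np.full(n, np.inf)
    binder_idx = rng.choice(n, size=config.n_binders, replace=False)
    lo, hi = config.binder_kd_range
    kd[binder_idx] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_binders))

    stickiness = np.zeros((n, len(RESINS)))
    a, b = config.sticky_beta
    for j in range(len(RESINS)):
        mask = rng.random(n) < config.sticky_prevalence
        stickiness[mask, j] = rng.beta(a, b, size=int(mask.sum()))
    # planted parasites: strong, single-resin stickiness on non-binder clones
    non_binders = np.setdiff1d(np.arange(n), binder_idx)
    if config.n_parasites:
        parasite_idx = rng.choice(non_binders, size=config.n_parasites, replace=False)
        lo_s, hi_s = config.parasite_sigma_range
        for k, idx in enumerate(parasite_idx):
            stickiness[idx, k % len(RESINS)] = rng.uniform(lo_s, hi_s)

    fitness = rng.lognormal(mean=0.0, sigma=config.fitness_sigma, size=n)

    return ClonePool(
        dna=np.array(dna_list, dtype=object),
        peptides=np.array(pep_list, dtype=object),
        abundance=abundance,
        kd=kd,
        stickiness=stickiness,
        fitness=fitness,
    )


# ---------------------------------------------------------------------------
# selection rounds


def run_round(
    pool: ClonePool,
    spec: RoundSpec,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> ClonePool:
    """One capture→wash→elute→amplify cycle; returns the post-amplification
    pool.  With ``amp_noise_tau == 0`` the update is deterministic."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    target = spec.target_ug * config.target_scale
    with np.errstate(invalid="ignore"):
        theta = np.where(np.isfinite(pool.kd), target / (target + pool.kd), 0.0)
    sigma = pool.stickiness[:, RESINS.index(spec.resin)]

    pass_factor = (1.0 - sigma) ** config.k_neg if spec.negative_selection else 1.0
    capture = 1.0 - (1.0 - theta) * (1.0 - sigma) * (1.0 - config.c0)
    retention = config.q_ns + (1.0 - config.q_ns) * np.maximum(theta, sigma)
    eluted = pool.abundance * pass_factor * capture * retention ** spec.washes

    if eluted.sum() == 0:
        raise EmptyElutionError(
            f"{spec.strategy} round {spec.round_index}: all clones washed away"
        )
    amplified = eluted * pool.fitness
    if config.amp_noise_tau > 0:
        amplified = amplified * np.exp(rng.normal(0.0, config.amp_noise_tau, len(pool)))
    return pool.with_abundance(amplified / amplified.sum())


def sample_counts(
    pool: ClonePool, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial read counts per clone at the given sequencing depth."""
    if depth <= 0:
        raise ValueError("sequencing depth must be positive")
    return rng.multinomial(depth, pool.abundance)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _inject_errors(seq_matrix: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. per-base substitutions on a (reads, length) uint8 char matrix.
    A hit base is replaced by one of the three other bases uniformly."""
    if rate <= 0:
        return seq_matrix
    mask = rng.random(seq_matrix.shape) < rate
    n_err = int(mask.sum())
    if n_err == 0:
        return seq_matrix
    offsets = rng.integers(1, 4, size=n_err)
    original = seq_matrix[mask]
    base_idx = np.searchsorted(_BASES, original)
    seq_matrix[mask] = _BASES[(base_idx + offsets) % 4]
    return seq_matrix


def reads_from_counts(
    pool: ClonePool,
    counts: np.ndarray,
    spec: RoundSpec,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[str, str, str]]:
    """Emit one read per counted clone copy, with substitution errors.

    Returns ``(title, sequence, quality)`` tuples; the title carries the
    round's index pair in the Illumina ``1:N:0:i7+i5`` convention.
    """
    clone_idx = np.repeat(np.arange(len(pool)), counts)

    full = [config.schema.flank5 + d + config.schema.flank3 for d in pool.dna]
    read_len = len(full[0])
    char_lookup = np.frombuffer(
        "".join(full).encode("ascii"), dtype=np.uint8
    ).reshape(len(pool), read_len)
    matrix = char_lookup[clone_idx].copy()
    matrix = _inject_errors(matrix, config.error_rate, rng)

    qual = config.quality_char * read_len
    tag = f"1:N:0:{spec.i7}+{spec.i5}"
    records = []
    for i, row in enumerate(matrix):
        title = f"SIM:{spec.strategy}:{spec.round_index}:{i + 1} {tag}"
        records.append((title, row.tobytes().decode("ascii"), qual))
    return records


def sequence_pool(
    pool: ClonePool,
    spec: RoundSpec,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str, str]]:
    """Simulate single-read sequencing: multinomial sampling at the round's
    depth followed by per-base substitution errors at ``error_rate``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    counts = sample_counts(pool, spec.depth, rng)
    return reads_from_counts(pool, counts, spec, config, rng)


def write_fastq(records: list[tuple[str, str, str]], path) -> None:
    """Write ``(title, seq, qual)`` tuples as a 4-line-record FASTQ file."""
    with open(path, "w") as fh:
        for title, seq, qual in records:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# whole campaigns


@dataclass
class CampaignResult:
    """Everything a campaign produced: final pools, per-sample reads or
    counts, and the ground-truth manifest (the recovery oracle)."""

    naive_pool: ClonePool
    pools: dict[tuple[str, int], ClonePool]
    reads: dict[tuple[str, int], list[tuple[str, str, str]]]
    counts: dict[tuple[str, int], np.ndarray]
    manifest: pd.DataFrame
    config: SimConfig

    def pool_table(self) -> pd.DataFrame:
        """Peptide-count table (strategy, round, peptide, count) built from
        the true multinomial counts — the error-free sequencing view."""
        rows = []
        for (strategy, rnd), counts in self.counts.items():
            pool = self.pools[(strategy, rnd)]
            nz = np.nonzero(counts)[0]
            agg: dict[str, int] = {}
            for i in nz:
                pep = pool.peptides[i]
                agg[pep] = agg.get(pep, 0) + int(counts[i])
            for pep, cnt in agg.items():
                rows.append((strategy, rnd, pep, cnt))
        return pd.DataFrame(rows, columns=["strategy", "round", "peptide", "count"])

    def demux_sheet(self) -> pd.DataFrame:
        rows = [
            (spec.i5, spec.i7, spec.strategy, spec.round_index)
            for rounds in self.config.campaigns.values()
            for spec in rounds
        ]
        return pd.DataFrame(rows, columns=["i5", "i7", "strategy", "round"])


def _build_manifest(pool: ClonePool) -> pd.DataFrame:
    data = {
        "peptide": pool.peptides,
        "dna": pool.dna,
        "kd_molar": pool.kd,
        "fitness": pool.fitness,
        "naive_abundance": pool.abundance,
    }
    for j, resin in enumerate(RESINS):
        data[f"sigma_{resin}"] = pool.stickiness[:, j]
    return pd.DataFrame(data)


def run_campaign(config: SimConfig, emit: str = "fastq") -> CampaignResult:
    """Run every strategy in the config from one shared naive pool.

    ``emit="fastq"`` sequences every round into read tuples; ``"counts"``
    keeps only the multinomial counts (fast path for large depths).  Only
    sampling/sequencing differs between the modes; the latent selection
    dynamics are identical.
    """
    if emit not in ("fastq", "counts"):
        raise ValueError(f"emit must be 'fastq' or 'counts', got {emit!r}")
    if not config.campaigns:
        raise ValueError("at least one campaign is required")
    rng = np.random.default_rng(config.seed)
    naive = generate_naive_library(config, rng)

    pools: dict[tuple[str, int], ClonePool] = {}
    reads: dict[tuple[str, int], list[tuple[str, str, str]]] = {}
    counts: dict[tuple[str, int], np.ndarray] = {}
    for strategy, rounds in config.campaigns.items():
        pool = naive
        for spec in sorted(rounds, key=lambda r: r.round_index):
            pool = run_round(pool, spec, config, rng)
            key = (strategy, spec.round_index)
            pools[key] = pool
            counts[key] = sample_counts(pool, spec.depth, rng)
            if emit == "fastq":
                reads[key] = reads_from_counts(pool, counts[key], spec, config, rng)
    return CampaignResult(
        naive_pool=naive,
        pools=pools,
        reads=reads,
        counts=counts,
        manifest=_build_manifest(naive),
        config=config,
    )
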