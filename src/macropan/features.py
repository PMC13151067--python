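"""Physicochemical descriptors and 2-D embedding of selected peptides.

Descriptors per peptide: GRAVY (mean Kyte–Doolittle hydropathy), net charge
at a stated pH (Henderson–Hasselbalch over ionizable side chains, termini
optional), aliphatic index (Ikai's mole-fraction formula over A/V/I/L),
length, and the monomer-frequency vector over the 20+n token alphabet.
Non-canonical tokens such as AcrK carry explicit scale overrides.

The descriptor matrix is z-scored and embedded to 2-D (UMAP by default, a
deterministic PCA projection as an alternative), then density-clustered
with DBSCAN — the "islands" view of enriched selection pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import parse_tokens

__all__ = [
    "ScaleSet",
    "default_scales",
    "gravy",
    "net_charge",
    "aliphatic_index",
    "descriptor_table",
    "Embedding",
    "embed_and_cluster",
]


class ScaleError(KeyError):
    """A residue token has no value in the active scale set."""


# Kyte & Doolittle hydropathy
_KD_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# EMBOSS-style side-chain pKa values; sign +1 basic, -1 acidic
_PKA_SIDE = {
    "D": (3.9, -1), "E": (4.1, -1), "C": (8.5, -1), "Y": (10.1, -1),
    "H": (6.5, +1), "K": (10.8, +1), "R": (12.5, +1),
}
_PKA_NTERM = 8.6
_PKA_CTERM = 3.6

# Ikai aliphatic-index weights (relative side-chain volumes)
_ALIPHATIC = {"A": 1.0, "V": 2.9, "I": 3.9, "L": 3.9}


@dataclass(frozen=True)
class ScaleSet:
    """Residue-token → scale values, with overrides for ncAA tokens.

    ``ncaa_overrides`` maps a token to a ``(hydropathy, pka_entry,
    aliphatic_weight)`` triple; ``pka_entry`` is ``(pKa, sign)`` or ``None``
    for a non-ionizable side chain.
    """

    hydropathy: dict[str, float] = field(default_factory=lambda: dict(_KD_HYDROPATHY))
    pka_side: dict[str, tuple[float, int]] = field(default_factory=lambda: dict(_PKA_SIDE))
    pka_nterm: float = _PKA_NTERM
    pka_cterm: float = _PKA_CTERM
    aliphatic: dict[str, float] = field(default_factory=lambda: dict(_ALIPHATIC))
    ncaa_overrides: dict[str, tuple[float, tuple[float, int] | None, float]] = field(
        default_factory=dict
    )

    def hydropathy_of(self, token: str) -> float:
        if token in self.ncaa_overrides:
            return self.ncaa_overrides[token][0]
        try:
            return self.hydropathy[token]
        except KeyError:
            raise ScaleError(f"no hydropathy value for token {token!r}") from None

    def pka_of(self, token: str) -> tuple[float, int] | None:
        if token in self.ncaa_overrides:
            return self.ncaa_overrides[token][1]
        if token in self.pka_side:
            return self.pka_side[token]
        if token in self.hydropathy:
            return None
        raise ScaleError(f"unknown token {token!r}")

    def aliphatic_of(self, token: str) -> float:
        if token in self.ncaa_overrides:
            return self.ncaa_overrides[token][2]
        if token in self.aliphatic:
            return self.aliphatic[token]
        if token in self.hydropathy:
            return 0.0
        raise ScaleError(f"unknown token {token!r}")


def default_scales() -> ScaleSet:
    """Kyte–Doolittle hydropathy, EMBOSS-style pKa set, Ikai aliphatic
    weights, plus the AcrK override: lysine-like hydropathy (-3.9) but no
    ionizable side chain — acryloylation caps the ε-amine — and zero
    aliphatic weight."""
    return ScaleSet(ncaa_overrides={"AcrK": (-3.9, None, 0.0)})


def gravy(peptide: str | tuple[str, ...], scales: ScaleSet | None = None) -> float:
    """Grand average of hydropathy: mean per-token hydropathy."""
    scales = scales or default_scales()
    tokens = parse_tokens(peptide)
    if not tokens:
        raise ValueError("empty peptide")
    return float(np.mean([scales.hydropathy_of(t) for t in tokens]))


def net_charge(
    peptide: str | tuple[str, ...],
    ph: float = 7.0,
    scales: ScaleSet | None = None,
    include_termini: bool = False,
) -> float:
    """Henderson–Hasselbalch net charge at the given pH.

    Each basic group contributes ``+1 / (1 + 10^(pH - pKa))``, each acidic
    group ``-1 / (1 + 10^(pKa - pH))``.  Termini are included only when
    requested (a cyclized or displayed peptide often has none free).
    """
    if not 0 < ph < 14:
        raise ValueError(f"pH must lie in (0, 14), got {ph}")
    scales = scales or default_scales()
    tokens = parse_tokens(peptide)
    if not tokens:
        raise ValueError("empty peptide")
    charge = 0.0
    for token in tokens:
        entry = scales.pka_of(token)
        if entry is None:
            continue
        pka, sign = entry
        if sign > 0:
            charge += 1.0 / (1.0 + 10 ** (ph - pka))
        else:
            charge -= 1.0 / (1.0 + 10 ** (pka - ph))
    if include_termini:
        charge += 1.0 / (1.0 + 10 ** (ph - scales.pka_nterm))
        charge -= 1.0 / (1.0 + 10 ** (scales.pka_cterm - ph))
    return charge


def aliphatic_index(
    peptide: str | tuple[str, ...], scales: ScaleSet | None = None
) -> float:
    """Ikai aliphatic index: ``100 * (fA*1.0 + fV*2.9 + (fI+fL)*3.9)`` with
    mole fractions f; ncAA tokens use their override weight (default 0)."""
    scales = scales or default_scales()
    tokens = parse_tokens(peptide)
    if not tokens:
        raise ValueError("empty peptide")
    return float(100.0 * np.mean([scales.aliphatic_of(t) for t in tokens]))


def descriptor_table(
    peptides: list[str],
    scales: ScaleSet | None = None,
    ph: float = 7.0,
    include_termini: bool = False,
) -> pd.DataFrame:
    """Per-peptide descriptor matrix, indexed by serialized peptide string.

    Columns: ``gravy``, ``net_charge``, ``aliphatic_index``, ``length`` and
    one ``f_<token>`` monomer-frequency column per token observed in the
    input (frequencies sum to 1 per row).
    """
    scales = scales or default_scales()
    token_lists = [parse_tokens(p) for p in peptides]
    alphabet = sorted({t for toks in token_lists for t in toks})
    rows = []
    for pep, tokens in zip(peptides, token_lists):
        n = len(tokens)
        row = {
            "gravy": gravy(tokens, scales),
            "net_charge": net_charge(tokens, ph, scales, include_termini),
            "aliphatic_index": aliphatic_index(tokens, scales),
            "length": float(n),
        }
        for tok in alphabet:
            row[f"f_{tok}"] = tokens.count(tok) / n
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(peptides, name="peptide"))


@dataclass
class Embedding:
    """2-D embedding with density-cluster labels and full provenance."""

    coordinates: pd.DataFrame   # columns x, y, cluster; indexed by peptide
    method: str
    params: dict
    seed: int
    dropped_columns: list[str]
    feature_means: pd.Series
    feature_stds: pd.Series


def embed_and_cluster(
    descriptors: pd.DataFrame,
    method: str = "umap",
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    eps: float = 0.5,
    min_samples: int = 5,
) -> Embedding:
    """Z-score the descriptor matrix, embed to 2-D, DBSCAN-cluster.

    ``method="umap"`` runs the UMAP algorithm with a fixed random state;
    ``method="pca"`` is a deterministic principal-component projection for
    fully reproducible tests.  Zero-variance columns are dropped before
    scaling.  Cluster label -1 marks noise points.
    """
    from sklearn.cluster import DBSCAN

    if len(descriptors) < 5:
        raise ValueError("embedding needs at least 5 peptides")
    values = descriptors.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad = descriptors.index[~np.isfinite(values).all(axis=1)][0]
        raise ValueError(f"non-finite descriptor for peptide {bad!r}")

    means = descriptors.mean(axis=0)
    stds = descriptors.std(axis=0, ddof=0)
    keep = stds > 0
    dropped = list(descriptors.columns[~keep])
    if keep.sum() == 0:
        # fully degenerate input: every peptide identical in feature space
        coords = np.zeros((len(descriptors), 2))
        labels = np.zeros(len(descriptors), dtype=int)
    else:
        z = (descriptors.loc[:, keep] - means[keep]) / stds[keep]
        z = z.to_numpy(dtype=float)
        if method == "umap":
            import umap

            nn = min(n_neighbors, len(descriptors) - 1)
            reducer = umap.UMAP(
                n_components=2,
                n_neighbors=nn,
                min_dist=min_dist,
                random_state=seed,
            )
            coords = np.asarray(reducer.fit_transform(z), dtype=float)
        elif method == "pca":
            from sklearn.decomposition import PCA

            coords = PCA(n_components=min(2, z.shape[1]), random_state=seed).fit_transform(z)
            if coords.shape[1] == 1:
                coords = np.column_stack([coords[:, 0], np.zeros(len(coords))])
        else:
            raise ValueError(f"unknown embedding method {method!r}")
        labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(coords)

    frame = pd.DataFrame(
        {"x": coords[:, 0], "y": coords[:, 1], "cluster": labels},
        index=descriptors.index,
    )
    return Embedding(
        coordinates=frame,
        method=method,
        params={
            "n_neighbors": n_neighbors,
            "min_dist": min_dist,
            "eps": eps,
            "min_samples": min_samples,
        },
        seed=seed,
        dropped_columns=dropped,
        feature_means=means,
        feature_stds=stds,
    )
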