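"""Genotype→phenotype decoding for displayed macrocyclic peptide libraries.

A phage-display library is defined by a scaffold pattern of fixed and
randomized residue positions, a degenerate-codon scheme per randomized
position (typically NNK), an optional amber-suppression map reassigning a
stop codon to a non-canonical amino acid (ncAA) token, and the constant
flanking DNA used to amplify the variable region out of the phagemid.

Residue tokens are strings, never bare characters: canonical residues are
the 20 single letters, ncAAs are multi-character tokens such as ``"AcrK"``
(Nε-acryloyl-lysine).  A token sequence serializes unambiguously with ncAA
tokens parenthesized, e.g. ``"CWRVFIWGQGP(AcrK)"``.

Conventions: peptide positions are 1-based; DNA intervals are 0-based
half-open.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import yaml
from Bio.Data import CodonTable, IUPACData

__all__ = [
    "SchemaError",
    "SequenceRejected",
    "GeneticCode",
    "SuppressionMap",
    "FixedPosition",
    "RandomPosition",
    "LibrarySchema",
    "expand_degenerate_codon",
    "translate_with_suppression",
    "matches_scaffold",
    "parse_tokens",
    "format_tokens",
    "standard_genetic_code",
    "acrk_10mer_schema",
    "camcbt_12mer_schema",
]

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
STOP = "*"

#: default constant flanks used by the simulator when a schema file does not
#: supply them (the amplicon's primer-defined constant regions).
DEFAULT_FLANK5 = "GCTAGCTCTGGTGGC"
DEFAULT_FLANK3 = "GGTGGAGGTTCTACT"


class SchemaError(ValueError):
    """A library schema, codon scheme or suppression map is malformed."""


class SequenceRejected(ValueError):
    """A DNA sequence cannot be decoded to a scaffold peptide.

    ``reason`` is one of ``"frame"``, ``"ambiguous"``, ``"stop"`` — the
    same vocabulary the ingest statistics use.
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True)
class GeneticCode:
    """Codon→residue map for the 64 standard codons; stops map to ``"*"``."""

    codon_to_residue: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.codon_to_residue) != 64:
            raise SchemaError(
                f"genetic code must have 64 codons, got {len(self.codon_to_residue)}"
            )
        if self.stop_codons != frozenset({"TAA", "TAG", "TGA"}):
            raise SchemaError(f"unexpected stop codons: {sorted(self.stop_codons)}")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, r in self.codon_to_residue.items() if r == STOP)

    def __getitem__(self, codon: str) -> str:
        return self.codon_to_residue[codon]


def standard_genetic_code() -> GeneticCode:
    """The standard nuclear genetic code (NCBI table 1)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for codon in table.stop_codons:
        mapping[codon] = STOP
    return GeneticCode(mapping)


@dataclass(frozen=True)
class SuppressionMap:
    """Stop-codon reassignments, e.g. amber suppression ``TAG → "AcrK"``.

    Every overridden codon must be a stop of the base code, and every token
    must be a non-canonical multi-character name (a single canonical letter
    would make the 20+n alphabet ambiguous).
    """

    overrides: dict[str, str] = field(default_factory=dict)

    def validate(self, code: GeneticCode) -> None:
        for codon, token in self.overrides.items():
            if codon not in code.stop_codons:
                raise SchemaError(f"suppressed codon {codon!r} is not a stop codon")
            if not token or token in CANONICAL_RESIDUES:
                raise SchemaError(f"invalid ncAA token {token!r} for codon {codon}")

    def __contains__(self, codon: str) -> bool:
        return codon in self.overrides

    def __getitem__(self, codon: str) -> str:
        return self.overrides[codon]


@dataclass(frozen=True)
class FixedPosition:
    """A scaffold position with a fixed residue token and its DNA codon."""

    residue: str
    codon: str


@dataclass(frozen=True)
class RandomPosition:
    """A randomized scaffold position encoded by a degenerate codon scheme."""

    scheme: str = "NNK"


# standard IUPAC degenerate alphabet (Biopython also maps the non-standard
# "X"; excluded here so schema files stay strictly IUPAC)
_IUPAC_DNA = {
    k.upper(): v.upper()
    for k, v in IUPACData.ambiguous_dna_values.items()
    if k.upper() in set("ACGTRYSWKMBDHVN")
}


def expand_degenerate_codon(scheme: str) -> frozenset[str]:
    """Expand an IUPAC-degenerate 3-letter codon into its concrete codons.

    ``|NNK| == 32``, ``|NNN| == 64``, ``|NNB| == 48``.
    """
    if len(scheme) != 3:
        raise SchemaError(f"codon scheme must have length 3, got {scheme!r}")
    scheme = scheme.upper()
    per_pos = []
    for letter in scheme:
        if letter not in _IUPAC_DNA:
            raise SchemaError(f"non-IUPAC letter {letter!r} in codon scheme {scheme!r}")
        per_pos.append(_IUPAC_DNA[letter])
    return frozenset("".join(c) for c in itertools.product(*per_pos))


def translate_with_suppression(
    dna: str, code: GeneticCode, sup: SuppressionMap
) -> tuple[str, ...]:
    """Translate DNA codon-wise, applying suppression overrides before the
    base code; any unsuppressed stop rejects the sequence.

    Raises :class:`SequenceRejected` with reason ``"frame"`` (length not a
    multiple of 3), ``"ambiguous"`` (non-ACGT base) or ``"stop"``.
    """
    dna = dna.upper()
    if len(dna) % 3 != 0:
        raise SequenceRejected("frame", f"length {len(dna)}")
    if not re.fullmatch(r"[ACGT]*", dna):
        raise SequenceRejected("ambiguous", dna)
    tokens: list[str] = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        if codon in sup:
            tokens.append(sup[codon])
            continue
        residue = code[codon]
        if residue == STOP:
            raise SequenceRejected("stop", f"codon {codon} at nt {i}")
        tokens.append(residue)
    return tuple(tokens)


def parse_tokens(peptide: str | tuple[str, ...] | list[str]) -> tuple[str, ...]:
    """Parse a serialized token string such as ``"CWRVFIWGQGP(AcrK)"``.

    Single characters are canonical residues; parenthesized groups are ncAA
    tokens.  Token tuples/lists pass through unchanged.
    """
    if not isinstance(peptide, str):
        return tuple(peptide)
    tokens: list[str] = []
    i = 0
    while i < len(peptide):
        ch = peptide[i]
        if ch == "(":
            j = peptide.find(")", i)
            if j < 0:
                raise SchemaError(f"unbalanced parenthesis in {peptide!r}")
            if j == i + 1:
                raise SchemaError(f"empty ncAA token in {peptide!r}")
            tokens.append(peptide[i + 1 : j])
            i = j + 1
        elif ch == ")":
            raise SchemaError(f"unbalanced parenthesis in {peptide!r}")
        else:
            tokens.append(ch)
            i += 1
    return tuple(tokens)


def format_tokens(tokens: tuple[str, ...] | list[str] | str) -> str:
    """Serialize a token sequence; ncAA tokens are parenthesized."""
    if isinstance(tokens, str):
        tokens = parse_tokens(tokens)
    return "".join(t if len(t) == 1 else f"({t})" for t in tokens)


@dataclass(frozen=True)
class LibrarySchema:
    """A displayed library: scaffold pattern, codon schemes, suppression, flanks."""

    name: str
    positions: tuple[FixedPosition | RandomPosition, ...]
    suppression: SuppressionMap = field(default_factory=SuppressionMap)
    code: GeneticCode = field(default_factory=standard_genetic_code)
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3

    def __post_init__(self) -> None:
        if not self.flank5 or not self.flank3:
            raise SchemaError("flanking DNA must be nonempty")
        self.suppression.validate(self.code)
        for i, pos in enumerate(self.positions, start=1):
            if isinstance(pos, FixedPosition):
                tok = self._decode_codon(pos.codon)
                if tok is None or tok != pos.residue:
                    raise SchemaError(
                        f"fixed position {i}: codon {pos.codon} does not encode "
                        f"{pos.residue!r}"
                    )
            else:
                expand_degenerate_codon(pos.scheme)  # validates the scheme

    def _decode_codon(self, codon: str) -> str | None:
        """Residue token a single codon yields under this schema, or None for
        an unsuppressed stop."""
        if codon in self.suppression:
            return self.suppression[codon]
        residue = self.code[codon]
        return None if residue == STOP else residue

    @property
    def length(self) -> int:
        """Scaffold length in residues."""
        return len(self.positions)

    @property
    def variable_region_nt(self) -> int:
        """Expected variable-region length in nucleotides (3 per position)."""
        return 3 * self.length

    def producible_tokens(self, pos: FixedPosition | RandomPosition) -> frozenset[str]:
        """Residue tokens a scaffold position can display."""
        if isinstance(pos, FixedPosition):
            return frozenset({pos.residue})
        tokens = set()
        for codon in expand_degenerate_codon(pos.scheme):
            tok = self._decode_codon(codon)
            if tok is not None:
                tokens.add(tok)
        return frozenset(tokens)

    def codon_choices(self, pos: FixedPosition | RandomPosition) -> tuple[str, ...]:
        """Concrete codons the simulator may draw at a position (sorted)."""
        if isinstance(pos, FixedPosition):
            return (pos.codon,)
        return tuple(sorted(expand_degenerate_codon(pos.scheme)))

    def matches_scaffold(self, peptide: str | tuple[str, ...]) -> bool:
        tokens = parse_tokens(peptide)
        if len(tokens) != self.length:
            return False
        return all(
            tok in self.producible_tokens(pos)
            for tok, pos in zip(tokens, self.positions)
        )

    # ---- config (YAML) round trip -------------------------------------

    def to_dict(self) -> dict:
        pattern = []
        for pos in self.positions:
            if isinstance(pos, FixedPosition):
                pattern.append({"fixed": pos.residue, "codon": pos.codon})
            else:
                pattern.append({"random": pos.scheme})
        return {
            "name": self.name,
            "pattern": pattern,
            "suppression": dict(self.suppression.overrides),
            "flank5": self.flank5,
            "flank3": self.flank3,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "LibrarySchema":
        positions: list[FixedPosition | RandomPosition] = []
        for entry in data["pattern"]:
            if "fixed" in entry:
                positions.append(FixedPosition(entry["fixed"], entry["codon"]))
            elif "random" in entry:
                n = int(entry.get("count", 1))
                positions.extend(RandomPosition(entry["random"]) for _ in range(n))
            else:
                raise SchemaError(f"pattern entry must be fixed or random: {entry}")
        return cls(
            name=data["name"],
            positions=tuple(positions),
            suppression=SuppressionMap(dict(data.get("suppression", {}))),
            flank5=data.get("flank5", DEFAULT_FLANK5),
            flank3=data.get("flank3", DEFAULT_FLANK3),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "LibrarySchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def matches_scaffold(peptide: str | tuple[str, ...], schema: LibrarySchema) -> bool:
    """True iff the peptide fits the schema's scaffold (total function)."""
    return schema.matches_scaffold(peptide)


def acrk_10mer_schema(flank5: str = DEFAULT_FLANK5, flank3: str = DEFAULT_FLANK3) -> LibrarySchema:
    """The amber-suppressed 10-mer library: Cys, ten NNK positions, and a
    TAG codon read through as AcrK — the acryloyl group closes a thioether
    macrocycle with the N-terminal cysteine in vivo."""
    return LibrarySchema(
        name="acrk-10mer",
        positions=(FixedPosition("C", "TGT"),)
        + tuple(RandomPosition("NNK") for _ in range(10))
        + (FixedPosition("AcrK", "TAG"),),
        suppression=SuppressionMap({"TAG": "AcrK"}),
        flank5=flank5,
        flank3=flank3,
    )


def camcbt_12mer_schema(flank5: str = DEFAULT_FLANK5, flank3: str = DEFAULT_FLANK3) -> LibrarySchema:
    """The chemically cyclized 12-mer library: twelve NNK positions flanked
    by an N-terminal and an internal cysteine (CX12C), cyclized post-
    expression by a bifunctional linker.  No suppression: an in-frame amber
    codon truncates the displayed peptide, so such clones are rejected."""
    return LibrarySchema(
        name="camcbt-12mer",
        positions=(FixedPosition("C", "TGT"),)
        + tuple(RandomPosition("NNK") for _ in range(12))
        + (FixedPosition("C", "TGT"),),
        suppression=SuppressionMap({}),
        flank5=flank5,
        flank3=flank3,
    )
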