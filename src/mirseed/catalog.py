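"""Seed extraction and the seed-sharing census over a mature-miRNA catalog.

The 5' "seed" of a mature miRNA (canonically nucleotides 2-7) dominates
target recognition, so two miRNAs with identical seeds are expected to share
a targetome even when the rest of their sequences diverge (the miR-210 /
miR-147b configuration).  This module extracts seed windows from mature
sequences, groups a catalog of miRNAs by seed, and summarises how often a
seed is shared between miRNAs and whether sharing miRNAs belong to the same
annotated family.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "RNA_ALPHABET",
    "MatureMiRNA",
    "SeedSpec",
    "SEED_2_7",
    "SEED_2_8",
    "SEED_1_8",
    "SeedCatalog",
    "CensusSummary",
    "normalize_rna",
    "extract_seed",
    "build_seed_catalog",
    "census_summary",
    "family_concordance",
    "census_table",
]

RNA_ALPHABET = frozenset("ACGU")

#: longest mature miRNA a seed window may be defined on
_MAX_SEED_END = 26


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T->U.  Raises ValueError on non-RNA characters."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return s


def _parse_arm(mirna_id: str) -> str:
    if mirna_id.endswith("-5p"):
        return "5p"
    if mirna_id.endswith("-3p"):
        return "3p"
    return "unknown"


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA sequence (5'->3') with arm and optional family."""

    id: str
    sequence: str
    arm: str = "unknown"
    family: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if self.arm == "unknown":
            object.__setattr__(self, "arm", _parse_arm(self.id))
        if self.arm not in ("5p", "3p", "unknown"):
            raise ValueError(f"invalid arm {self.arm!r}")

    @property
    def effective_family(self) -> str:
        """Family label, falling back to a singleton family named after the id.

        Unannotated miRNAs can then never contribute a same-family match.
        """
        return self.family if self.family is not None else f"__singleton__{self.id}"


@dataclass(frozen=True)
class SeedSpec:
    """A seed window on the mature sequence: 1-based start and length.

    Canonical instances: (2, 6) = "seed 2-7", (2, 7) = "seed 2-8",
    (1, 8) = "seed 1-8".
    """

    start: int = 2
    length: int = 6

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("seed start must be >= 1")
        if self.length not in (6, 7, 8) and not (1 <= self.length <= 8):
            raise ValueError("seed length must be between 1 and 8")
        if self.start + self.length - 1 > _MAX_SEED_END:
            raise ValueError("seed window extends beyond a mature miRNA")

    @property
    def end(self) -> int:
        """1-based inclusive end position."""
        return self.start + self.length - 1

    @property
    def name(self) -> str:
        return f"seed{self.start}-{self.end}"


SEED_2_7 = SeedSpec(2, 6)
SEED_2_8 = SeedSpec(2, 7)
SEED_1_8 = SeedSpec(1, 8)


def extract_seed(seq: str, spec: SeedSpec = SEED_2_7) -> str:
    """Return the seed window of ``seq`` (5'->3', 1-based, inclusive).

    >>> extract_seed("CUGUGCGUGUGACAGCGGCUGA")  # hsa-miR-210
    'UGUGCG'
    """
    s = normalize_rna(seq)
    if len(s) < spec.end:
        raise ValueError(
            f"sequence of length {len(s)} too short for {spec.name}"
        )
    return s[spec.start - 1 : spec.end]


@dataclass
class SeedCatalog:
    """Mapping seed string -> the miRNAs carrying it, under one SeedSpec."""

    spec: SeedSpec
    entries: dict[str, list[MatureMiRNA]] = field(default_factory=dict)

    @property
    def n_mirnas(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def members(self, seed: str) -> list[MatureMiRNA]:
        return self.entries.get(seed, [])


def build_seed_catalog(
    mirnas: list[MatureMiRNA],
    spec: SeedSpec = SEED_2_7,
    collapse_identical_sequences: bool = False,
) -> SeedCatalog:
    """Group miRNAs by their extracted seed.

    Paralogous loci often deposit the same mature sequence under several
    names; by default each name counts as a distinct miRNA (the census is
    keyed by miRNA name).  With ``collapse_identical_sequences`` identical
    mature sequences are counted once, keeping the lexicographically first id.
    """
    ids = [m.id for m in mirnas]
    dup = [i for i, c in Counter(ids).items() if c > 1]
    if dup:
        raise ValueError(f"duplicate miRNA ids: {sorted(dup)[:5]}")

    pool = mirnas
    if collapse_identical_sequences:
        by_seq: dict[str, MatureMiRNA] = {}
        for m in sorted(mirnas, key=lambda m: m.id):
            by_seq.setdefault(m.sequence, m)
        pool = list(by_seq.values())

    entries: dict[str, list[MatureMiRNA]] = {}
    for m in sorted(pool, key=lambda m: m.id):
        entries.setdefault(extract_seed(m.sequence, spec), []).append(m)
    return SeedCatalog(spec=spec, entries=entries)


@dataclass
class CensusSummary:
    """How many seeds exist, and how widely each is shared."""

    n_mirnas: int
    n_distinct_seeds: int
    n_unique_seeds: int
    n_shared_seeds: int
    histogram: dict[int, int]  # miRNAs-per-seed k -> number of seeds
    same_family_fraction: dict[int, float]  # k -> fraction of shared seeds

    def __post_init__(self) -> None:
        assert self.n_unique_seeds + self.n_shared_seeds == self.n_distinct_seeds
        assert sum(self.histogram.values()) == self.n_distinct_seeds


def _round_half_up_pct(x: float) -> float:
    """Percent to one decimal, rounding half up (34.55 -> 34.6)."""
    return float(Decimal(repr(100.0 * x)).quantize(Decimal("0.1"), ROUND_HALF_UP))


def census_summary(catalog: SeedCatalog) -> CensusSummary:
    """Count distinct, unique (one carrier) and shared (>= 2 carriers) seeds."""
    if not catalog.entries:
        raise ValueError("empty catalog")
    histogram: dict[int, int] = {}
    same_family: dict[int, int] = {}
    for members in catalog.entries.values():
        k = len(members)
        histogram[k] = histogram.get(k, 0) + 1
        if k >= 2:
            fams = {m.effective_family for m in members}
            if len(fams) == 1:
                same_family[k] = same_family.get(k, 0) + 1
    n_distinct = len(catalog.entries)
    n_unique = histogram.get(1, 0)
    frac = {
        k: same_family.get(k, 0) / histogram[k]
        for k in sorted(histogram)
        if k >= 2
    }
    return CensusSummary(
        n_mirnas=catalog.n_mirnas,
        n_distinct_seeds=n_distinct,
        n_unique_seeds=n_unique,
        n_shared_seeds=n_distinct - n_unique,
        histogram=dict(sorted(histogram.items())),
        same_family_fraction=frac,
    )


def family_concordance(catalog: SeedCatalog) -> pd.DataFrame:
    """Per sharing level k >= 2: shared seeds, same-family seeds, percent.

    A shared seed is "same-family" when every carrier has the same family
    label; miRNAs without a label count as their own singleton family.
    Percent is reported to one decimal, rounding half up.
    """
    counts: dict[int, list[int]] = {}
    for members in catalog.entries.values():
        k = len(members)
        if k < 2:
            continue
        row = counts.setdefault(k, [0, 0])
        row[0] += 1
        if len({m.effective_family for m in members}) == 1:
            row[1] += 1
    rows = [
        {
            "k": k,
            "n_shared_seeds": shared,
            "n_same_family": same,
            "same_family_pct": _round_half_up_pct(same / shared),
        }
        for k, (shared, same) in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows, columns=["k", "n_shared_seeds", "n_same_family", "same_family_pct"]
    )


def census_table(catalog: SeedCatalog) -> pd.DataFrame:
    """Per-seed carrier table: counts and names split by arm, plus families.

    Columns: seed, count_mirna, count_mirna_5p, mirna_5p, count_mirna_3p,
    mirna_3p, count_fam, fam_5p, fam_3p.  Multi-valued cells are
    comma-joined; empty cells hold ".".
    """
    rows = []
    for seed in sorted(catalog.entries):
        members = catalog.entries[seed]
        m5 = [m for m in members if m.arm == "5p"]
        m3 = [m for m in members if m.arm == "3p"]
        fams = sorted({m.family for m in members if m.family is not None})
        f5 = sorted({m.family for m in m5 if m.family is not None})
        f3 = sorted({m.family for m in m3 if m.family is not None})

        def join(xs: list[str]) -> str:
            return ",".join(xs) if xs else "."

        rows.append(
            {
                "seed": seed,
                "count_mirna": len(members),
                "count_mirna_5p": len(m5),
                "mirna_5p": join([m.id for m in m5]),
                "count_mirna_3p": len(m3),
                "mirna_3p": join([m.id for m in m3]),
                "count_fam": len(fams),
                "fam_5p": join(f5),
                "fam_3p": join(f3),
            }
        )
    return pd.DataFrame(rows)
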