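"""Complementary seed-match scanning of transcript regions.

A seed site is a window of an mRNA region that pairs antiparallel
Watson-Crick to the miRNA seed; the exact site is the seed's reverse
complement.  The scanner optionally tolerates G:U wobble pairs (seed G
opposite site U, or seed U opposite site G), which is how a single C->U
seed substitution (miR-147b -> miR-147a) preserves all exact sites as
one-wobble sites.  Pairing-extent annotation extends the duplex outward
from a matched seed and measures 3'-supplementary pairing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .catalog import (
    SEED_2_7,
    MatureMiRNA,
    SeedSpec,
    extract_seed,
    normalize_rna,
)

__all__ = [
    "revcomp_rna",
    "pairs_watson_crick",
    "pairs_wobble",
    "SeedMatcher",
    "seed_site_pattern",
    "TranscriptRegions",
    "TargetSite",
    "PairingExtent",
    "scan_region",
    "scan_transcriptome",
    "predicted_target_sets",
    "pairing_extent",
]

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

REGIONS = ("5UTR", "CDS", "3UTR")


def revcomp_rna(seq: str) -> str:
    """Reverse complement of an RNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def pairs_watson_crick(a: str, b: str) -> bool:
    return (a, b) in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"))


def pairs_wobble(seed_base: str, site_base: str) -> bool:
    """G:U wobble, oriented: seed G pairs site U, seed U pairs site G."""
    return (seed_base, site_base) in (("G", "U"), ("U", "G"))


@dataclass
class SeedMatcher:
    """Accepts mRNA windows (5'->3', seed length) pairing the seed antiparallel.

    Seed position i (1-based from the miRNA 5' end) faces window position
    L - i + 1.  Every position must pair Watson-Crick except at most
    ``max_wobbles`` G:U pairs when ``allow_wobble`` is set.  ``match``
    returns the wobble count on acceptance and None otherwise.
    """

    seed: str
    allow_wobble: bool = False
    max_wobbles: int = 1

    def __post_init__(self) -> None:
        self.seed = normalize_rna(self.seed)
        self.exact_site = revcomp_rna(self.seed)
        # site position j faces seed position L - j + 1; allowed site bases
        # per position, wobble partner second
        allowed = []
        for seed_base in reversed(self.seed):
            wc = seed_base.translate(_COMPLEMENT)
            choices = wc
            if self.allow_wobble and seed_base in "GU":
                choices += "U" if seed_base == "G" else "G"
            allowed.append(choices)
        self._allowed = allowed
        self._regex = re.compile(
            "(?=(" + "".join(f"[{c}]" for c in allowed) + "))"
        )

    def match(self, window: str) -> int | None:
        if len(window) != len(self.seed):
            return None
        wobbles = 0
        for site_base, allowed in zip(window, self._allowed):
            if site_base == allowed[0]:
                continue
            if len(allowed) > 1 and site_base == allowed[1]:
                wobbles += 1
            else:
                return None
        if wobbles > (self.max_wobbles if self.allow_wobble else 0):
            return None
        return wobbles

    def finditer(self, seq: str):
        """Yield (0-based window start, wobble count) over all windows."""
        if self.allow_wobble:
            for m in self._regex.finditer(seq):
                w = self.match(m.group(1))
                if w is not None:
                    yield m.start(), w
        else:
            start = seq.find(self.exact_site)
            while start != -1:
                yield start, 0
                start = seq.find(self.exact_site, start + 1)


def seed_site_pattern(
    seed: str, allow_wobble: bool = False, max_wobbles: int = 1
) -> SeedMatcher:
    """Build a site matcher for a seed (factory kept for a functional API)."""
    return SeedMatcher(seed, allow_wobble=allow_wobble, max_wobbles=max_wobbles)


@dataclass
class TranscriptRegions:
    """Region sequences of one transcript; any of 5UTR/CDS/3UTR may be absent.

    3'UTR position 1 is the first base after the stop codon.
    """

    transcript_id: str
    regions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.regions:
            if name not in REGIONS:
                raise ValueError(f"unknown region {name!r}")
        self.regions = {
            k: v.upper().replace("T", "U") for k, v in self.regions.items()
        }


@dataclass(frozen=True)
class TargetSite:
    """One seed-match occurrence: region-local 1-based start, wobble count.

    ``distance_to_stop`` is start-1 for 3'UTR sites and
    -(region length - start + 1) for CDS sites (None elsewhere).
    """

    transcript_id: str
    region: str
    start: int
    spec: SeedSpec
    wobbles: int = 0
    distance_to_stop: int | None = None


def _distance_to_stop(region: str, start: int, region_len: int) -> int | None:
    if region == "3UTR":
        return start - 1
    if region == "CDS":
        return -(region_len - start + 1)
    return None


def scan_region(
    region_seq: str,
    seed: str,
    spec: SeedSpec = SEED_2_7,
    allow_wobble: bool = False,
    max_wobbles: int = 1,
    transcript_id: str = "",
    region: str = "3UTR",
    require_t1a: bool = False,
) -> list[TargetSite]:
    """All seed sites in one region, ascending start, overlaps allowed.

    Windows containing characters outside {A,C,G,U} (e.g. N) never match.
    ``require_t1a`` additionally demands an A on the mRNA opposite miRNA
    position 1 (the base just 3'-ward of the matched window); off by default
    since the search is a plain complementary match.
    """
    seq = region_seq.upper().replace("T", "U")
    matcher = seed_site_pattern(seed, allow_wobble, max_wobbles)
    n = len(seq)
    sites = []
    for pos, w in matcher.finditer(seq):
        if require_t1a and spec.start > 1:
            t1 = pos + spec.end - 1  # 0-based mRNA index opposite position 1
            if t1 >= n or seq[t1] != "A":
                continue
        sites.append(
            TargetSite(
                transcript_id=transcript_id,
                region=region,
                start=pos + 1,
                spec=spec,
                wobbles=w,
                distance_to_stop=_distance_to_stop(region, pos + 1, n),
            )
        )
    return sites


def longest_class_only(site_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge site tables from several seed classes, keeping one class per site.

    ``site_tables`` maps spec name -> table from :func:`scan_transcriptome`.
    A site of a shorter class is dropped when a longer class reports a site
    for the same (mirna, transcript, region) whose window contains it.
    """
    ordered = sorted(
        site_tables.items(),
        key=lambda kv: -int(kv[0].split("-")[-1]),  # longer class first
    )
    kept: list[pd.DataFrame] = []
    covered: set[tuple] = set()
    for _, table in ordered:
        if table.empty:
            continue
        length = int(table["spec"].iloc[0].split("-")[-1]) - int(
            table["spec"].iloc[0].replace("seed", "").split("-")[0]
        ) + 1
        rows = []
        for row in table.itertuples(index=False):
            span = range(row.start, row.start + length)
            key_base = (row.mirna, row.transcript, row.region)
            if any((*key_base, p) in covered for p in span):
                continue
            rows.append(row)
            covered.update((*key_base, p) for p in span)
        kept.append(pd.DataFrame(rows, columns=table.columns))
    return (
        pd.concat(kept, ignore_index=True)
        if kept
        else pd.DataFrame(
            columns=["mirna", "transcript", "region", "start", "spec",
                     "wobbles", "distance_to_stop"]
        )
    )


def scan_transcriptome(
    transcripts: list[TranscriptRegions],
    mirnas: list[MatureMiRNA],
    spec: SeedSpec = SEED_2_7,
    regions: tuple[str, ...] = ("3UTR",),
    allow_wobble: bool = False,
    max_wobbles: int = 1,
    min_sites: int = 1,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Scan every (miRNA, transcript, region) combination.

    Returns the site table (one row per site) and per-miRNA predicted target
    sets: transcripts with >= ``min_sites`` sites over the selected regions.
    Multiple sites in one transcript still yield one set membership.
    """
    for r in regions:
        if r not in REGIONS:
            raise ValueError(f"unknown region {r!r}")
    rows: list[dict] = []
    target_sets: dict[str, set[str]] = {}
    for mirna in sorted(mirnas, key=lambda m: m.id):
        seed = extract_seed(mirna.sequence, spec)
        matcher = seed_site_pattern(seed, allow_wobble, max_wobbles)
        targets: set[str] = set()
        for tr in transcripts:
            n_sites = 0
            for region in regions:
                seq = tr.regions.get(region)
                if not seq:
                    continue
                n = len(seq)
                for pos, w in matcher.finditer(seq):
                    n_sites += 1
                    rows.append(
                        {
                            "mirna": mirna.id,
                            "transcript": tr.transcript_id,
                            "region": region,
                            "start": pos + 1,
                            "spec": spec.name,
                            "wobbles": w,
                            "distance_to_stop": _distance_to_stop(
                                region, pos + 1, n
                            ),
                        }
                    )
            if n_sites >= min_sites:
                targets.add(tr.transcript_id)
        target_sets[mirna.id] = targets
    table = pd.DataFrame(
        rows,
        columns=[
            "mirna", "transcript", "region", "start", "spec", "wobbles",
            "distance_to_stop",
        ],
    )
    return table, target_sets


def predicted_target_sets(
    transcripts: list[TranscriptRegions],
    mirnas: list[MatureMiRNA],
    spec: SeedSpec = SEED_2_7,
    regions: tuple[str, ...] = ("3UTR",),
    allow_wobble: bool = False,
    max_wobbles: int = 1,
) -> dict[str, set[str]]:
    """Per-miRNA predicted target sets without materialising the site table.

    Exact scans reduce to substring containment of the seed's reverse
    complement, which is much faster than enumerating sites.
    """
    sets: dict[str, set[str]] = {}
    for mirna in mirnas:
        seed = extract_seed(mirna.sequence, spec)
        if not allow_wobble:
            site = revcomp_rna(seed)
            sets[mirna.id] = {
                tr.transcript_id
                for tr in transcripts
                if any(site in tr.regions.get(r, "") for r in regions)
            }
        else:
            matcher = seed_site_pattern(seed, True, max_wobbles)
            sets[mirna.id] = {
                tr.transcript_id
                for tr in transcripts
                if any(
                    next(matcher.finditer(tr.regions.get(r, "")), None)
                    is not None
                    for r in regions
                )
            }
    return sets


@dataclass(frozen=True)
class PairingExtent:
    """Contiguous pairing interval around a seed site, in miRNA coordinates.

    ``extent`` is the (first, last) miRNA position of the maximal contiguous
    paired run containing the seed.  ``supplementary_3p`` is the longest
    Watson-Crick run the miRNA 3' region (positions >= 13) can form against
    the 30 nt of mRNA upstream (5'-ward) of the site — the side the miRNA
    3' end faces in the antiparallel duplex.
    """

    transcript_id: str
    site: TargetSite
    extent: tuple[int, int]
    supplementary_3p: int


_SUPPLEMENTARY_FROM = 13
_SUPPLEMENTARY_WINDOW = 30


def _longest_common_substring(a: str, b: str) -> int:
    if not a or not b:
        return 0
    best = 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def pairing_extent(
    mirna_seq: str,
    region_seq: str,
    site: TargetSite,
    allow_wobble_in_extent: bool = False,
) -> PairingExtent:
    """Extend pairing outward from a matched seed window.

    miRNA position m faces region position ``site.start + spec.end - m``
    (antiparallel register fixed by the seed).  Extension stops at the first
    non-pairing position on each side; the miRNA 5'-terminal nucleotide is
    held by Argonaute and never extends the duplex unless it lies inside the
    seed window itself.
    """
    mirna = normalize_rna(mirna_seq)
    region = region_seq.upper().replace("T", "U")
    spec = site.spec
    if site.start < 1 or site.start + spec.length - 1 > len(region):
        raise ValueError("site out of region bounds")

    def paired(m: int) -> bool:
        r = site.start + spec.end - m
        if not (1 <= r <= len(region)) or not (1 <= m <= len(mirna)):
            return False
        a, b = mirna[m - 1], region[r - 1]
        return pairs_watson_crick(a, b) or (
            allow_wobble_in_extent and pairs_wobble(a, b)
        )

    lo = spec.start
    while lo - 1 >= 2 and paired(lo - 1):
        lo -= 1
    hi = spec.end
    while hi + 1 <= len(mirna) and paired(hi + 1):
        hi += 1

    window = region[max(0, site.start - 1 - _SUPPLEMENTARY_WINDOW) : site.start - 1]
    tail = mirna[_SUPPLEMENTARY_FROM - 1 :]
    supp = _longest_common_substring(tail, revcomp_rna(window))
    return PairingExtent(
        transcript_id=site.transcript_id,
        site=site,
        extent=(lo, hi),
        supplementary_3p=supp,
    )
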