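"""Readers and writers for the catalog, region, DE-table and prediction
dialects.

Mature miRNA catalogs arrive as miRBase-style FASTA (the id is the first
whitespace-delimited header token, e.g. ``>hsa-miR-210 MIMAT0000267 ...``);
family annotations as miFam.dat records (AC/ID/MI lines) or two-column TSV;
transcript regions as per-region FASTA or one FASTA plus CDS boundaries;
differential-expression and prediction tables as TSV.  Tables are written
tab-delimited with a header and "." for missing values.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .catalog import MatureMiRNA
from .enrichment import DERecord, PredictionSource
from .scan import TranscriptRegions

__all__ = [
    "read_mature_fasta",
    "read_family_file",
    "family_for",
    "assign_families",
    "read_de_table",
    "read_predictions",
    "read_regions_fasta",
    "read_regions_with_boundaries",
    "strip_transcript_version",
    "write_table",
    "read_table",
    "write_fasta",
]

_VERSION_RE = re.compile(r"\.\d+$")


def strip_transcript_version(transcript_id: str) -> str:
    """Drop a trailing RefSeq-style version suffix (NM_001080.3 -> NM_001080)."""
    return _VERSION_RE.sub("", transcript_id)


def read_mature_fasta(
    path: str | Path, species_prefix: str | None = None
) -> list[MatureMiRNA]:
    """Mature miRNAs from a miRBase-dialect FASTA, optionally one species.

    Sequences are uppercased and T->U normalized; the arm is parsed from a
    -5p/-3p id suffix.
    """
    mirnas = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if species_prefix and not rec.id.startswith(species_prefix):
            continue
        try:
            mirnas.append(MatureMiRNA(id=rec.id, sequence=str(rec.seq)))
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
    return mirnas


def read_family_file(path: str | Path) -> dict[str, str]:
    """miRNA id -> family id, from miFam.dat or a two-column TSV.

    The miFam dialect groups records as AC/ID lines followed by MI lines
    (``MI   MI0000071  hsa-mir-17``), terminated by ``//``; the TSV dialect
    is ``family_id<TAB>mirna_id``.  Conflicting duplicate assignments raise.
    """
    path = Path(path)
    text = path.read_text()
    mapping: dict[str, str] = {}

    def assign(mirna_id: str, family: str, where: str) -> None:
        if mirna_id in mapping and mapping[mirna_id] != family:
            raise ValueError(
                f"{where}: conflicting family for {mirna_id!r}: "
                f"{mapping[mirna_id]!r} vs {family!r}"
            )
        mapping[mirna_id] = family

    if re.search(r"^(AC|ID|MI)\s", text, flags=re.M):
        family = None
        for ln, line in enumerate(text.splitlines(), start=1):
            if line.startswith("ID"):
                family = line.split(None, 1)[1].strip()
            elif line.startswith("MI"):
                parts = line.split()
                if family is None or len(parts) < 3:
                    raise ValueError(f"{path}:{ln}: malformed MI line")
                assign(parts[2], family, f"{path}:{ln}")
            elif line.startswith("//"):
                family = None
        return mapping

    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
        assign(parts[1], parts[0], f"{path}:{ln}")
    return mapping


def family_for(mirna_id: str, families: dict[str, str]) -> str | None:
    """Family lookup with mature->precursor name fallback.

    miFam.dat annotates precursor names (``hsa-mir-17``); mature names carry
    ``miR`` capitalisation and arm suffixes, so the lookup tries the exact
    id, the id without its -5p/-3p suffix, and the miR->mir precursor form.
    """
    candidates = [mirna_id]
    stripped = re.sub(r"-[53]p$", "", mirna_id)
    candidates.append(stripped)
    candidates.append(stripped.replace("miR", "mir"))
    # mature duplicates like hsa-miR-121a* carry a trailing star
    candidates.append(stripped.replace("miR", "mir").rstrip("*"))
    for c in candidates:
        if c in families:
            return families[c]
    return None


def assign_families(
    mirnas: list[MatureMiRNA], families: dict[str, str]
) -> list[MatureMiRNA]:
    """Attach family labels to a catalog; unmatched miRNAs stay unlabelled."""
    return [
        MatureMiRNA(
            id=m.id, sequence=m.sequence, arm=m.arm,
            family=family_for(m.id, families),
        )
        for m in mirnas
    ]


DE_COLUMNS = ["transcript_id", "A", "M", "p", "adjP"]


def read_de_table(
    path: str | Path, strip_versions: bool = True
) -> list[DERecord]:
    """Differential-expression records from a TSV.

    Requires the header columns transcript_id, A, M, p, adjP.  Rows with
    non-numeric or out-of-range values are rejected (naming the row);
    duplicate transcripts (multiple probes) collapse to the row with the
    smallest adjP.
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("A", "M", "p", "adjP"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad:
            raise ValueError(f"{path}: non-numeric {col!r} in rows {bad[:5]}")
        df[col] = coerced
    for col in ("p", "adjP"):
        bad = df.index[(df[col] < 0) | (df[col] > 1)].tolist()
        if bad:
            raise ValueError(
                f"{path}: {col!r} outside [0, 1] in rows {bad[:5]}"
            )
    if strip_versions:
        df["transcript_id"] = df["transcript_id"].map(strip_transcript_version)
    df = (
        df.sort_values(["adjP", "p"], kind="mergesort")
        .drop_duplicates("transcript_id", keep="first")
        .sort_index()
    )
    return [
        DERecord(
            transcript_id=r.transcript_id, A=float(r.A), M=float(r.M),
            p=float(r.p), adjP=float(r.adjP),
        )
        for r in df.itertuples(index=False)
    ]


def read_predictions(
    path: str | Path, name: str | None = None, strip_versions: bool = True
) -> PredictionSource:
    """A miRNA-transcript pair list (``mirna_id<TAB>transcript_id``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if "mirna_id" not in cols or "transcript_id" not in cols:
        raise ValueError(
            f"{path}: expected columns mirna_id, transcript_id (got {cols})"
        )
    tids = df["transcript_id"]
    if strip_versions:
        tids = tids.map(strip_transcript_version)
    return PredictionSource(
        name=name or Path(path).stem,
        pairs=set(zip(df["mirna_id"], tids)),
    )


def _read_fasta_map(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_regions_fasta(
    utr3: str | Path | None = None,
    cds: str | Path | None = None,
    utr5: str | Path | None = None,
) -> list[TranscriptRegions]:
    """Transcript regions from up to three per-region FASTA files."""
    region_maps = {}
    if utr5:
        region_maps["5UTR"] = _read_fasta_map(utr5)
    if cds:
        region_maps["CDS"] = _read_fasta_map(cds)
    if utr3:
        region_maps["3UTR"] = _read_fasta_map(utr3)
    if not region_maps:
        raise ValueError("at least one region FASTA is required")
    ids = sorted(set().union(*[m.keys() for m in region_maps.values()]))
    return [
        TranscriptRegions(
            transcript_id=tid,
            regions={
                region: seqs[tid]
                for region, seqs in region_maps.items()
                if tid in seqs
            },
        )
        for tid in ids
    ]


def read_regions_with_boundaries(
    fasta: str | Path, boundaries: str | Path
) -> list[TranscriptRegions]:
    """Full transcript FASTA plus a TSV of CDS boundaries.

    The TSV columns are transcript, cds_start, cds_end (1-based, closed);
    5'UTR is everything before cds_start, 3'UTR everything after cds_end.
    """
    seqs = _read_fasta_map(fasta)
    bounds = pd.read_csv(boundaries, sep="\t", dtype={"transcript": str})
    for col in ("transcript", "cds_start", "cds_end"):
        if col not in bounds.columns:
            raise ValueError(f"{boundaries}: missing column {col!r}")
    out = []
    for row in bounds.itertuples(index=False):
        if row.transcript not in seqs:
            raise ValueError(f"no sequence for transcript {row.transcript!r}")
        seq = seqs[row.transcript]
        s, e = int(row.cds_start), int(row.cds_end)
        if not (1 <= s <= e <= len(seq)):
            raise ValueError(f"{row.transcript}: CDS bounds out of range")
        regions = {"CDS": seq[s - 1 : e]}
        if s > 1:
            regions["5UTR"] = seq[: s - 1]
        if e < len(seq):
            regions["3UTR"] = seq[e:]
        out.append(
            TranscriptRegions(transcript_id=row.transcript, regions=regions)
        )
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV with header; missing values become "."."""
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", na_values=["."])


def write_fasta(records: dict[str, str] | list, path: str | Path) -> None:
    """Write sequences as FASTA; accepts a dict or MatureMiRNA list."""
    if isinstance(records, list):
        records = {m.id: m.sequence for m in records}
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n{records[name]}\n")
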