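"""Hypergeometric target-set enrichment of differential-expression signatures.

Given a differential-expression table from a miRNA-overexpression experiment
(versus a negative control), transcripts are classified into an expressed
universe and up/down-regulated categories at fixed thresholds.  Each
candidate miRNA's predicted target set is then tested for over-representation
in a category with the hypergeometric upper tail

    P(X >= k),  X ~ Hypergeometric(N, K, n)

where N is the universe size, K the predicted targets in the universe,
n the category size and k the predicted targets in the category, with
Benjamini-Hochberg correction across miRNAs.  Fold enrichment is
(k/n) / (K/N).  A transfected miRNA — and any miRNA sharing its seed —
should surface at the top of the down-regulated ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DERecord",
    "DEClassification",
    "PredictionSource",
    "classify_de",
    "classify_de_table",
    "hypergeom_tail",
    "bh_adjust",
    "enrich_experiment",
    "regional_enrichment",
    "target_set_overlap",
]

ENRICHMENT_COLUMNS = [
    "mirna", "source", "category", "k", "n", "K", "N",
    "p_hyper", "adjP", "fold", "minus_log10_adjP",
]


@dataclass(frozen=True)
class DERecord:
    """One transcript's differential-expression summary.

    A is the log2 average expression, M the log2 fold change versus the
    negative control; p and adjP are the raw and multiplicity-adjusted
    p-values of the comparison.
    """

    transcript_id: str
    A: float
    M: float
    p: float
    adjP: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.adjP <= 1.0):
            raise ValueError(
                f"{self.transcript_id}: p-values must lie in [0, 1]"
            )
        if not (np.isfinite(self.A) and np.isfinite(self.M)):
            raise ValueError(f"{self.transcript_id}: A and M must be finite")


@dataclass
class DEClassification:
    """Expressed universe plus up/down-regulated transcript sets."""

    universe: set[str]
    down: set[str]
    up: set[str]
    a_min: float
    m_cut: float
    adjp_max: float

    def __post_init__(self) -> None:
        assert self.down <= self.universe and self.up <= self.universe
        assert not (self.down & self.up)

    def category(self, name: str) -> set[str]:
        return {"down": self.down, "up": self.up}[name]


@dataclass
class PredictionSource:
    """A named set of predicted (miRNA, transcript) pairs."""

    name: str
    pairs: set[tuple[str, str]] = field(default_factory=set)

    def targets_of(self, mirna_id: str) -> set[str]:
        return {t for m, t in self.pairs if m == mirna_id}

    @classmethod
    def from_target_sets(
        cls, name: str, target_sets: dict[str, set[str]]
    ) -> "PredictionSource":
        return cls(
            name=name,
            pairs={(m, t) for m, ts in target_sets.items() for t in ts},
        )

    def as_target_sets(self) -> dict[str, set[str]]:
        sets: dict[str, set[str]] = {}
        for m, t in self.pairs:
            sets.setdefault(m, set()).add(t)
        return sets


def classify_de(
    records: list[DERecord],
    a_min: float = 8.0,
    m_cut: float = 0.5,
    adjp_max: float = 0.05,
    universe_mode: str = "expressed",
) -> DEClassification:
    """Classify a DE table into universe / down / up at fixed thresholds.

    Universe = transcripts with A > a_min (``universe_mode="all"`` keeps every
    transcript instead); down = universe members with M < -m_cut and
    adjP < adjp_max; up symmetric with M > +m_cut.
    """
    ids = [r.transcript_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transcript ids (collapse probes first)")
    if universe_mode not in ("expressed", "all"):
        raise ValueError(f"unknown universe mode {universe_mode!r}")
    if universe_mode == "expressed":
        in_universe = [r for r in records if r.A > a_min]
    else:
        in_universe = list(records)
    if not in_universe:
        raise ValueError("degenerate input: empty universe")
    universe = {r.transcript_id for r in in_universe}
    down = {
        r.transcript_id
        for r in in_universe
        if r.M < -m_cut and r.adjP < adjp_max
    }
    up = {
        r.transcript_id
        for r in in_universe
        if r.M > m_cut and r.adjP < adjp_max
    }
    return DEClassification(
        universe=universe, down=down, up=up,
        a_min=a_min, m_cut=m_cut, adjp_max=adjp_max,
    )


def classify_de_table(
    table: pd.DataFrame,
    a_min: float = 8.0,
    m_cut: float = 0.5,
    adjp_max: float = 0.05,
    universe_mode: str = "expressed",
) -> DEClassification:
    """Vectorised :func:`classify_de` over a DE DataFrame.

    Expects columns ``transcript_id``, ``A``, ``M``, ``adjP`` (one row per
    transcript).
    """
    if table["transcript_id"].duplicated().any():
        raise ValueError("duplicate transcript ids (collapse probes first)")
    if universe_mode not in ("expressed", "all"):
        raise ValueError(f"unknown universe mode {universe_mode!r}")
    finite = np.isfinite(table["A"]) & np.isfinite(table["M"])
    expressed = (table["A"] > a_min) if universe_mode == "expressed" else finite
    in_universe = expressed & finite
    if not in_universe.any():
        raise ValueError("degenerate input: empty universe")
    sig = table["adjP"] < adjp_max
    down_mask = in_universe & sig & (table["M"] < -m_cut)
    up_mask = in_universe & sig & (table["M"] > m_cut)
    ids = table["transcript_id"]
    return DEClassification(
        universe=set(ids[in_universe]),
        down=set(ids[down_mask]),
        up=set(ids[up_mask]),
        a_min=a_min, m_cut=m_cut, adjp_max=adjp_max,
    )


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Inclusive upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"invalid hypergeometric bounds k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _enrich_one_source(
    declass: DEClassification,
    source: PredictionSource,
    mirna_ids: list[str],
    category: str,
) -> pd.DataFrame:
    cat = declass.category(category)
    N = len(declass.universe)
    n = len(cat)
    rows = []
    sets = source.as_target_sets()
    for mid in mirna_ids:
        targets = sets.get(mid, set()) & declass.universe
        K = len(targets)
        k = len(targets & cat)
        if K == 0:
            rows.append(
                dict(mirna=mid, source=source.name, category=category,
                     k=0, n=n, K=0, N=N, p_hyper=1.0, adjP=np.nan,
                     fold=np.nan, minus_log10_adjP=np.nan)
            )
            continue
        p = hypergeom_tail(k, n, K, N)
        fold = (k / n) / (K / N) if n > 0 else np.nan
        rows.append(
            dict(mirna=mid, source=source.name, category=category,
                 k=k, n=n, K=K, N=N, p_hyper=p, adjP=np.nan,
                 fold=fold, minus_log10_adjP=np.nan)
        )
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    testable = df["K"] > 0
    if testable.any():
        adj = bh_adjust(df.loc[testable, "p_hyper"].to_numpy())
        df.loc[testable, "adjP"] = adj
        with np.errstate(divide="ignore"):
            df.loc[testable, "minus_log10_adjP"] = -np.log10(adj)
    return df


def enrich_experiment(
    declass: DEClassification,
    sources: list[PredictionSource],
    mirna_ids: list[str],
    categories: tuple[str, ...] = ("down", "up"),
) -> pd.DataFrame:
    """One enrichment row per (miRNA, source, category).

    K counts only universe members; BH is applied across miRNAs within one
    (source, category) family, excluding untestable K=0 rows.  Rows are
    ranked by adjP ascending, then fold descending, then miRNA id.
    """
    mirna_ids = sorted(set(mirna_ids))
    parts = [
        _enrich_one_source(declass, src, mirna_ids, cat)
        for src in sources
        for cat in categories
    ]
    df = pd.concat(parts, ignore_index=True)
    df = df.sort_values(
        by=["source", "category", "adjP", "fold", "mirna"],
        ascending=[True, True, True, False, True],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    return df


def regional_enrichment(
    declass: DEClassification,
    site_table: pd.DataFrame,
    bin_width: int = 200,
    category: str = "down",
    max_bins: int | None = None,
) -> pd.DataFrame:
    """Enrichment profile along the transcript: 3'UTR distance-to-stop bins,
    CDS and 5'UTR as whole regions.

    Predicted target sets are recomputed per region/bin from the site table
    (3'UTR sites binned by ``distance_to_stop``); each bin is then tested as
    in :func:`enrich_experiment`.  Empty bins are skipped.
    """
    if site_table.empty:
        return pd.DataFrame(columns=["bin", *ENRICHMENT_COLUMNS])
    mirna_ids = sorted(site_table["mirna"].unique())
    out = []
    for region, sub in site_table.groupby("region"):
        if region == "3UTR":
            dist = sub["distance_to_stop"].astype(int)
            bins = dist // bin_width
            for b, bsub in sub.groupby(bins):
                if max_bins is not None and b >= max_bins:
                    continue
                label = f"3UTR[{b * bin_width},{(b + 1) * bin_width})"
                out.append((label, bsub))
        else:
            out.append((region, sub))
    parts = []
    for label, sub in out:
        sets = {
            m: set(g["transcript"]) for m, g in sub.groupby("mirna")
        }
        src = PredictionSource.from_target_sets(label, sets)
        part = _enrich_one_source(declass, src, mirna_ids, category)
        part.insert(0, "bin", label)
        parts.append(part)
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["bin", *ENRICHMENT_COLUMNS]
    )


def target_set_overlap(experiments: dict[str, set[str]]) -> pd.DataFrame:
    """Pairwise overlap of per-miRNA target sets.

    Percent overlap is |A∩B| / min(|A|, |B|) — the share of the smaller
    signature that is common; Venn partition counts are reported alongside
    the Jaccard index.  Undefined percents (an empty set) are NaN.
    """
    if len(experiments) < 2:
        raise ValueError("need at least two experiments")
    rows = []
    for (na, a), (nb, b) in combinations(sorted(experiments.items()), 2):
        inter = len(a & b)
        union = len(a | b)
        rows.append(
            {
                "set_a": na,
                "set_b": nb,
                "size_a": len(a),
                "size_b": len(b),
                "only_a": len(a - b),
                "only_b": len(b - a),
                "intersection": inter,
                "jaccard": inter / union if union else np.nan,
                "overlap_pct": (
                    100.0 * inter / min(len(a), len(b))
                    if min(len(a), len(b)) > 0
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
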