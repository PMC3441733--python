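"""Synthetic miRNA catalogs, transcriptomes with planted seed sites, and
overexpression differential-expression tables.

The generator emulates the design of a miRNA-transfection microarray study:
one miRNA is overexpressed against a negative control (three biological
replicates per arm), transcripts carrying a complementary seed site in their
3'UTR are preferentially repressed by a fixed log2 shift, and the analysis
must recover the transfected miRNA from its target-set enrichment among
decoy miRNAs.  All randomness flows through one seeded generator, so every
output is reproducible from (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .catalog import SEED_2_7, MatureMiRNA, SeedSpec, extract_seed
from .enrichment import (
    PredictionSource,
    bh_adjust,
    classify_de_table,
    enrich_experiment,
)
from .scan import TranscriptRegions, predicted_target_sets, revcomp_rna

__all__ = [
    "SharingGroup",
    "SimulationConfig",
    "simulate_mirna_catalog",
    "simulate_transcriptome",
    "simulate_overexpression",
    "recovery_experiment",
]

_BASES = "ACGU"

#: mature sequence of hsa-miR-210 (miRBase v16); its 2-7 seed is UGUGCG
MIR210_SEQUENCE = "CUGUGCGUGUGACAGCGGCUGA"


@dataclass(frozen=True)
class SharingGroup:
    """Part of a seed-sharing plan: ``count`` seeds each carried by ``k``
    miRNAs, all of one family or of ``k`` distinct families."""

    k: int
    count: int
    same_family: bool = False


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror the transfection design the analysis assumes: 5000
    expressed transcripts, 4% carrying a planted 3'UTR seed site for the
    transfected miRNA, a mean log2 repression of 2 with replicate noise
    0.25, and three replicates per arm.
    """

    rng_seed: int = 0
    # --- miRNA catalog ---
    n_unique_seeds: int = 40
    sharing_plan: tuple[SharingGroup, ...] = (
        SharingGroup(k=2, count=6, same_family=True),
        SharingGroup(k=2, count=6, same_family=False),
        SharingGroup(k=3, count=2, same_family=False),
    )
    mature_length: int = 22
    seed_spec: SeedSpec = SEED_2_7
    # --- transcriptome ---
    n_transcripts: int = 5000
    utr3_mean: float = 1000.0
    utr3_sd: float = 300.0
    utr3_min: int = 100
    utr5_length: int = 0
    cds_length: int = 0
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    planted_mirna_id: str = "sim-miR-planted"
    planted_sequence: str = MIR210_SEQUENCE
    target_fraction: float = 0.04
    sites_per_target: tuple[float, ...] = (0.6, 0.3, 0.1)  # P(1), P(2), ...
    max_site_distance: int | None = None  # cap planted distance to stop
    # --- expression model ---
    effect_mu: float = 2.0
    noise_sigma: float = 0.25
    n_replicates: int = 3
    unexpressed_fraction: float = 0.1
    a_mean: float = 10.0
    a_sd: float = 1.0
    a_min: float = 8.0
    repression_per_site: bool = False  # -mu * min(site count, 3) if set

    def __post_init__(self) -> None:
        if self.effect_mu < 0 or self.noise_sigma < 0:
            raise ValueError("effect size and noise must be non-negative")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValueError("target_fraction must lie in [0, 1]")
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")
        if self.n_transcripts < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")

    @property
    def n_mirnas(self) -> int:
        return self.n_unique_seeds + sum(
            g.k * g.count for g in self.sharing_plan
        )

    @property
    def planted_seed(self) -> str:
        return extract_seed(self.planted_sequence, self.seed_spec)


def _random_seeds(
    rng: np.random.Generator,
    n: int,
    length: int,
    exclude: set[str] = frozenset(),
) -> list[str]:
    """Distinct random RNA words of one length, avoiding ``exclude``."""
    if n + len(exclude) > 4 ** length:
        raise ValueError("sharing plan infeasible: not enough distinct seeds")
    out: list[str] = []
    seen = set(exclude)
    while len(out) < n:
        word = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
        if word not in seen:
            seen.add(word)
            out.append(word)
    return out


def _mature_from_seed(
    rng: np.random.Generator, seed: str, spec: SeedSpec, length: int
) -> str:
    flanks = rng.integers(0, 4, size=length)
    seq = [_BASES[i] for i in flanks]
    seq[spec.start - 1 : spec.end] = list(seed)
    return "".join(seq)


def simulate_mirna_catalog(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[MatureMiRNA]:
    """A miRNA catalog whose seed-sharing census equals the plan exactly.

    Unique-seed miRNAs each get their own family; each shared group gets one
    family (``same_family``) or one family per member.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    spec = config.seed_spec
    n_seeds = config.n_unique_seeds + sum(g.count for g in config.sharing_plan)
    seeds = _random_seeds(rng, n_seeds, spec.length)
    mirnas: list[MatureMiRNA] = []
    fam_counter = 0
    it = iter(seeds)
    for i in range(config.n_unique_seeds):
        seed = next(it)
        fam_counter += 1
        mirnas.append(
            MatureMiRNA(
                id=f"sim-miR-u{i + 1:03d}",
                sequence=_mature_from_seed(rng, seed, spec, config.mature_length),
                family=f"sim-fam-{fam_counter:03d}",
            )
        )
    for g_idx, group in enumerate(config.sharing_plan):
        for c in range(group.count):
            seed = next(it)
            if group.same_family:
                fam_counter += 1
                fams = [f"sim-fam-{fam_counter:03d}"] * group.k
            else:
                fams = []
                for _ in range(group.k):
                    fam_counter += 1
                    fams.append(f"sim-fam-{fam_counter:03d}")
            for j in range(group.k):
                mirnas.append(
                    MatureMiRNA(
                        id=f"sim-miR-g{g_idx + 1}s{c + 1}m{j + 1}",
                        sequence=_mature_from_seed(
                            rng, seed, spec, config.mature_length
                        ),
                        family=fams[j],
                    )
                )
    return mirnas


def _random_rna_blocks(
    rng: np.random.Generator, lengths: np.ndarray, probs
) -> list[str]:
    total = int(lengths.sum())
    if list(probs) == [0.25, 0.25, 0.25, 0.25]:
        idx = rng.integers(0, 4, size=total)
    else:
        idx = rng.choice(4, size=total, p=list(probs))
    big = bytes(np.frombuffer(b"ACGU", dtype=np.uint8)[idx]).decode()
    offsets = np.concatenate([[0], np.cumsum(lengths)]).astype(int)
    return [big[offsets[i] : offsets[i + 1]] for i in range(len(lengths))]


def simulate_transcriptome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[TranscriptRegions], pd.DataFrame]:
    """Random transcript regions with planted 3'UTR sites for the planted
    miRNA's seed.

    Exactly ``ceil(target_fraction * n_transcripts)`` transcripts receive at
    least one exact site (the seed's reverse complement) at uniformly random
    non-overlapping 3'UTR positions; the truth table lists every planted
    site.  Incidental background matches elsewhere are allowed and show up
    on rescan.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    n = config.n_transcripts
    lengths = np.maximum(
        np.round(rng.normal(config.utr3_mean, config.utr3_sd, size=n)),
        config.utr3_min,
    ).astype(int)
    utr3 = _random_rna_blocks(rng, lengths, config.base_probs)

    site = revcomp_rna(config.planted_seed)
    L = len(site)
    n_targets = math.ceil(config.target_fraction * n)
    target_idx = rng.choice(n, size=n_targets, replace=False)
    probs = np.asarray(config.sites_per_target)
    truth_rows = []
    for ti in target_idx:
        n_sites = int(rng.choice(len(probs), p=probs / probs.sum())) + 1
        limit = lengths[ti] - L + 1
        if config.max_site_distance is not None:
            limit = min(limit, config.max_site_distance - L + 2)
        if limit < n_sites:  # crude feasibility: need room for sites
            raise ValueError("3'UTR too short to host requested sites")
        seq = utr3[ti]
        placed: list[int] = []
        attempts = 0
        while len(placed) < n_sites:
            pos = int(rng.integers(0, limit))
            if all(abs(pos - q) >= L for q in placed):
                placed.append(pos)
            attempts += 1
            if attempts > 1000:
                raise ValueError("3'UTR too short to host requested sites")
        for pos in sorted(placed):
            seq = seq[:pos] + site + seq[pos + L :]
            truth_rows.append(
                {
                    "transcript": f"SIMT{ti + 1:06d}",
                    "region": "3UTR",
                    "start": pos + 1,
                    "mirna": config.planted_mirna_id,
                }
            )
        utr3[ti] = seq

    transcripts = []
    if config.utr5_length or config.cds_length:
        extra_lengths = np.full(
            n, config.utr5_length + config.cds_length, dtype=int
        )
        extra = _random_rna_blocks(rng, extra_lengths, config.base_probs)
    for i in range(n):
        regions = {"3UTR": utr3[i]}
        if config.utr5_length or config.cds_length:
            block = extra[i]
            if config.utr5_length:
                regions["5UTR"] = block[: config.utr5_length]
            if config.cds_length:
                regions["CDS"] = block[config.utr5_length :]
        transcripts.append(
            TranscriptRegions(transcript_id=f"SIMT{i + 1:06d}", regions=regions)
        )
    truth = pd.DataFrame(
        truth_rows, columns=["transcript", "region", "start", "mirna"]
    ).sort_values(["transcript", "start"]).reset_index(drop=True)
    return transcripts, truth


def simulate_overexpression(
    transcripts: list[TranscriptRegions],
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """An overexpression-vs-control DE table for the simulated transcriptome.

    Per transcript, ``n_replicates`` log-ratios are drawn from
    Normal(-mu * is_target, sigma); M is their mean and p comes from a
    one-sample location test of the replicates against zero (adjP by
    Benjamini-Hochberg).  Because the noise model is homoscedastic, the
    test uses the variance pooled across all transcripts — the same
    stabilisation a moderated array analysis achieves — so a handful of
    replicates still yields well-calibrated p-values: under the null the
    statistic is N(0, 1) to within the pooling error.  A is
    Normal(a_mean, a_sd) truncated above ``a_min`` except for a configurable
    unexpressed fraction.  In the noise-free limit (sigma = 0) targets have
    M = -mu exactly and p = 0.
    """
    if config.n_replicates < 2:
        raise ValueError("need at least two replicates for a location test")
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    ids = [tr.transcript_id for tr in transcripts]
    n = len(ids)
    is_target = np.isin(ids, truth["transcript"].unique())
    shift = np.where(is_target, -config.effect_mu, 0.0)
    if config.repression_per_site and len(truth):
        counts = truth.groupby("transcript").size()
        site_counts = pd.Series(0, index=ids).add(counts, fill_value=0)
        shift = -config.effect_mu * np.minimum(
            site_counts.loc[ids].to_numpy(), 3
        )
    reps = rng.normal(
        loc=shift[:, None], scale=config.noise_sigma,
        size=(n, config.n_replicates),
    )
    M = reps.mean(axis=1)
    var = reps.var(axis=1, ddof=1)
    sd_pool = math.sqrt(float(var.mean()))
    df = n * (config.n_replicates - 1)
    if sd_pool > 0:
        tstat = M / (sd_pool / math.sqrt(config.n_replicates))
        p = 2.0 * t_dist.sf(np.abs(tstat), df)
    else:
        p = np.where(M != 0, 0.0, 1.0)
    adjP = bh_adjust(p)

    unexpressed = rng.random(n) < config.unexpressed_fraction
    A = np.empty(n)
    todo = ~unexpressed
    while todo.any():  # rejection-sample the truncation above a_min
        draw = rng.normal(config.a_mean, config.a_sd, size=int(todo.sum()))
        A[todo] = draw
        todo = todo & (A <= config.a_min)
    A[unexpressed] = np.minimum(
        rng.normal(config.a_min - 2.0, config.a_sd, size=int(unexpressed.sum())),
        config.a_min,
    )
    return pd.DataFrame(
        {"transcript_id": ids, "A": A, "M": M, "p": p, "adjP": adjP}
    )


def _decoy_catalog(
    config: SimulationConfig,
    rng: np.random.Generator,
    n_decoys: int,
    coseed_decoy: bool,
) -> list[MatureMiRNA]:
    spec = config.seed_spec
    seeds = _random_seeds(
        rng, n_decoys, spec.length, exclude={config.planted_seed}
    )
    decoys = [
        MatureMiRNA(
            id=f"sim-miR-d{i + 1:03d}",
            sequence=_mature_from_seed(rng, s, spec, config.mature_length),
        )
        for i, s in enumerate(seeds)
    ]
    if coseed_decoy:
        decoys.append(
            MatureMiRNA(
                id="sim-miR-coseed",
                sequence=_mature_from_seed(
                    rng, config.planted_seed, spec, config.mature_length
                ),
            )
        )
    return decoys


def recovery_experiment(
    config: SimulationConfig,
    n_decoys: int = 50,
    n_runs: int = 200,
    coseed_decoy: bool = False,
    rng: np.random.Generator | None = None,
) -> dict:
    """Run the full simulate -> scan -> classify -> enrich pipeline
    repeatedly and summarise recovery of the planted miRNA.

    Reports the planted miRNA's rank distribution in the down-category
    enrichment (adjP, then fold, then id), the fraction of runs ranked
    first, and the decoy false-positive rate at adjP < 0.05.  With a
    co-seeded decoy its rank and statistics are tracked too.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    per_run = []
    for run in range(n_runs):
        child = np.random.default_rng(rng.integers(0, 2**31 - 1))
        planted = MatureMiRNA(
            id=config.planted_mirna_id, sequence=config.planted_sequence
        )
        decoys = _decoy_catalog(config, child, n_decoys, coseed_decoy)
        mirnas = [planted] + decoys
        transcripts, truth = simulate_transcriptome(config, child)
        de = simulate_overexpression(transcripts, truth, config, child)
        declass = classify_de_table(de, a_min=config.a_min)
        sets = predicted_target_sets(
            transcripts, mirnas, spec=config.seed_spec, regions=("3UTR",)
        )
        source = PredictionSource.from_target_sets("seed-match", sets)
        table = enrich_experiment(
            declass, [source], [m.id for m in mirnas], categories=("down",)
        )
        table = table.reset_index(drop=True)
        rank = int(
            table.index[table["mirna"] == config.planted_mirna_id][0]
        ) + 1
        decoy_rows = table[table["mirna"].str.startswith("sim-miR-d")]
        fp = float((decoy_rows["adjP"] < 0.05).sum() / len(decoy_rows))
        rec = {"run": run, "planted_rank": rank, "decoy_fp_rate": fp}
        if coseed_decoy:
            co = table[table["mirna"] == "sim-miR-coseed"].iloc[0]
            pl = table[table["mirna"] == config.planted_mirna_id].iloc[0]
            rec.update(
                coseed_rank=int(
                    table.index[table["mirna"] == "sim-miR-coseed"][0]
                ) + 1,
                coseed_equal_stats=bool(
                    co["k"] == pl["k"] and co["K"] == pl["K"]
                    and co["p_hyper"] == pl["p_hyper"]
                ),
            )
        per_run.append(rec)
    runs = pd.DataFrame(per_run)
    ranks = runs["planted_rank"].value_counts().sort_index()
    summary = {
        "n_runs": n_runs,
        "n_decoys": n_decoys,
        "rank_distribution": {int(k): int(v) for k, v in ranks.items()},
        "frac_rank1": float((runs["planted_rank"] == 1).mean()),
        "decoy_fp_rate": float(runs["decoy_fp_rate"].mean()),
        "runs": runs,
    }
    if coseed_decoy:
        summary["coseed_frac_equal_stats"] = float(
            runs["coseed_equal_stats"].mean()
        )
        summary["coseed_rank_distribution"] = {
            int(k): int(v)
            for k, v in runs["coseed_rank"].value_counts().sort_index().items()
        }
    return summary
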