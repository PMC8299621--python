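"""Synthetic transcripts and count tracks with planted, recoverable effects.

The generative model mirrors the analysis: per-site log10 cleavage score is
a linear function of feature values (computed by the real feature code)
plus Gaussian noise; degradome reads are Poisson with rate proportional to
gene abundance times the score, cap reads are Poisson around abundance, and
ribosome-protected-fragment reads concentrate in the CDS.

All randomness flows from ``SimConfig.seed`` through named
``numpy.random.default_rng`` streams, so reruns are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .feature_extraction import FeatureConfig, FeatureSpec, evaluate_specs, required_context
from .penalized_models import FittedModel
from .transcript_io import CountTrack, STOP_CODONS, Transcript

logger = logging.getLogger(__name__)

_NON_STOP_CODONS = tuple(
    c
    for c in ("".join((a, b, d)) for a in "ACGU" for b in "ACGU" for d in "ACGU")
    if c not in STOP_CODONS
)

# rng stream tags (mixed with the seed so stages draw independently)
_STREAM_TRANSCRIPTS = 1
_STREAM_ABUNDANCE = 2
_STREAM_DEGRADOME = 3
_STREAM_RIBOSOME = 4


@dataclass
class SimConfig:
    n_genes: int = 40
    utr5_len: tuple[int, int] = (20, 80)
    cds_codons: tuple[int, int] = (60, 160)
    utr3_len: tuple[int, int] = (20, 120)
    nt_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)  # ACGU

    abundance_mu: float = 5.0  # ln-scale lognormal parameters of abundance
    abundance_sigma: float = 0.6

    planted: list[tuple[FeatureSpec, float]] = field(default_factory=list)
    alpha0: float = 0.0
    sigma_eps: float = 0.5
    plant_standardized: bool = True  # betas act on z-scored feature values

    depth_degradome: float = 1.0
    depth_cap: float = 1.0
    depth_rpf: float = 0.2
    utr_rpf_rate: float = 0.05
    rpf_factor_sigma: float = 0.5

    site_context: int = 30  # flanking nucleotides required around a site
    site_density: float = 0.25  # fraction of eligible CDS positions used
    overdispersion: float = 0.0  # gamma-mixing CV; 0 = plain Poisson

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if min(self.depth_degradome, self.depth_cap, self.depth_rpf) <= 0:
            raise ValueError("all sequencing depths must be positive")
        if abs(sum(self.nt_probs) - 1.0) > 1e-9:
            raise ValueError("nucleotide probabilities must sum to 1")


@dataclass
class SimGroundTruth:
    abundance: pd.Series  # gene_id -> expected abundance
    sites: pd.DataFrame  # gene_id, position, true_log10_cs
    planted: pd.DataFrame  # feature, beta
    feature_values: pd.DataFrame  # realized (standardized) planted values per site


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _random_seq(rng: np.random.Generator, length: int, probs) -> str:
    return "".join(rng.choice(list("ACGU"), size=length, p=list(probs)))


def simulate_transcripts(config: SimConfig) -> dict[str, Transcript]:
    """Random transcripts whose CDS starts with AUG, ends with a stop codon,
    and contains no internal in-frame stop."""
    if config.cds_codons[0] < 2:
        raise ValueError("CDS needs at least 2 codons (start + stop)")
    rng = _rng(config, _STREAM_TRANSCRIPTS)
    out: dict[str, Transcript] = {}
    width = max(4, len(str(config.n_genes)))
    for i in range(config.n_genes):
        gid = f"g{i + 1:0{width}d}"
        u5 = int(rng.integers(config.utr5_len[0], config.utr5_len[1] + 1))
        nc = int(rng.integers(config.cds_codons[0], config.cds_codons[1] + 1))
        u3 = int(rng.integers(config.utr3_len[0], config.utr3_len[1] + 1))
        internal = rng.choice(_NON_STOP_CODONS, size=nc - 2)
        stop = rng.choice(STOP_CODONS)
        cds = "AUG" + "".join(internal) + str(stop)
        seq = (
            _random_seq(rng, u5, config.nt_probs)
            + cds
            + _random_seq(rng, u3, config.nt_probs)
        )
        out[gid] = Transcript(gid, seq, u5, u5 + 3 * nc)
    return out


def gene_abundances(config: SimConfig, gene_ids: list[str]) -> pd.Series:
    """Deterministic per-gene expected abundances (shared across stages)."""
    rng = _rng(config, _STREAM_ABUNDANCE)
    vals = rng.lognormal(config.abundance_mu, config.abundance_sigma, len(gene_ids))
    return pd.Series(vals, index=sorted(gene_ids), name="abundance")


def candidate_sites(
    transcripts: Mapping[str, Transcript], config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """CDS-internal positions with full flanking context, subsampled to the
    configured density."""
    rows = []
    m = config.site_context
    for gid in sorted(transcripts):
        t = transcripts[gid]
        lo = max(t.cds_start, m)
        hi = min(t.cds_end, t.length - m)
        positions = np.arange(lo, hi)
        if len(positions) == 0:
            continue
        keep = rng.random(len(positions)) < config.site_density
        for p in positions[keep]:
            rows.append((gid, int(p)))
    return pd.DataFrame(rows, columns=["gene_id", "position"])


def _poisson_counts(
    rng: np.random.Generator, rates: np.ndarray, overdispersion: float
) -> np.ndarray:
    rates = np.asarray(rates, dtype=float)
    if overdispersion > 0:
        shape = 1.0 / overdispersion**2
        rates = rates * rng.gamma(shape, 1.0 / shape, size=rates.shape)
    return rng.poisson(rates)


def simulate_degradome(
    transcripts: Mapping[str, Transcript],
    config: SimConfig,
    occupancy=None,
    feature_config: FeatureConfig | None = None,
) -> tuple[dict[str, CountTrack], dict[str, CountTrack], SimGroundTruth]:
    """Degradome and cap tracks plus the planted ground truth.

    Per candidate site, ``log10 CS = alpha0 + beta . x + eps`` with feature
    values ``x`` computed by the real extraction code on the planted specs
    (z-scored across sites when ``plant_standardized``); degradome reads are
    Poisson(abundance * 10**log10CS * depth), cap reads Poisson(abundance *
    cap_depth) placed at the transcript 5' end.
    """
    rng = _rng(config, _STREAM_DEGRADOME)
    feature_config = feature_config or FeatureConfig()
    sites = candidate_sites(transcripts, config, rng)
    if len(sites) == 0:
        raise ValueError("no candidate sites; relax lengths or density")

    specs = [s for s, _ in config.planted]
    betas = np.array([b for _, b in config.planted], dtype=float)
    if occupancy is None and any(s.category == "occupancy" for s in specs):
        dropped = [s.name for s in specs if s.category == "occupancy"]
        logger.warning(
            "no occupancy table supplied; planted occupancy specs skipped: %s",
            ", ".join(dropped),
        )
        keep = [i for i, s in enumerate(specs) if s.category != "occupancy"]
        specs = [specs[i] for i in keep]
        betas = betas[keep]
    m_req = required_context(specs)
    if m_req > config.site_context:
        raise ValueError(
            f"planted specs need +/-{m_req} context but site_context is "
            f"{config.site_context}"
        )
    if specs:
        X = evaluate_specs(sites, transcripts, occupancy, specs, feature_config)
        keep_cols = []
        for j, s in enumerate(specs):
            if np.std(X[:, j]) == 0:
                logger.warning("planted feature %s is constant; dropped", s.name)
            else:
                keep_cols.append(j)
        specs = [specs[j] for j in keep_cols]
        betas = betas[keep_cols]
        X = X[:, keep_cols]
        if config.plant_standardized and X.shape[1]:
            X = (X - X.mean(axis=0)) / X.std(axis=0)
    else:
        X = np.zeros((len(sites), 0))

    eps = rng.normal(0.0, config.sigma_eps, len(sites))
    log10_cs = config.alpha0 + (X @ betas if len(betas) else 0.0) + eps

    abundance = gene_abundances(config, sorted(transcripts))
    ab = sites["gene_id"].map(abundance).to_numpy()
    deg_reads = _poisson_counts(
        rng, ab * np.power(10.0, log10_cs) * config.depth_degradome, config.overdispersion
    )

    deg_tracks: dict[str, CountTrack] = {}
    for gid, grp in sites.assign(reads=deg_reads).groupby("gene_id"):
        counts = {
            int(p): int(c) for p, c in zip(grp["position"], grp["reads"]) if c > 0
        }
        deg_tracks[gid] = CountTrack(gid, "degradome", counts)

    cap_tracks: dict[str, CountTrack] = {}
    for gid in sorted(transcripts):
        total = int(rng.poisson(abundance[gid] * config.depth_cap))
        cap_tracks[gid] = CountTrack(gid, "cap", {0: total} if total > 0 else {})

    truth = SimGroundTruth(
        abundance=abundance,
        sites=sites.assign(true_log10_cs=log10_cs),
        planted=pd.DataFrame(
            {"feature": [s.name for s in specs], "beta": betas}
        ),
        feature_values=pd.DataFrame(X, columns=[s.name for s in specs]),
    )
    return deg_tracks, cap_tracks, truth


def simulate_ribosome(
    transcripts: Mapping[str, Transcript], config: SimConfig
) -> tuple[dict[str, CountTrack], pd.Series]:
    """RPF tracks with reads concentrated in the CDS.

    Per-position rate is ``abundance * factor * depth_rpf`` inside the CDS
    and that times ``utr_rpf_rate`` in the UTRs, where ``factor`` is a
    per-gene lognormal occupancy multiplier (also returned, for recovery
    checks)."""
    rng = _rng(config, _STREAM_RIBOSOME)
    abundance = gene_abundances(config, sorted(transcripts))
    factors = pd.Series(
        rng.lognormal(0.0, config.rpf_factor_sigma, len(transcripts)),
        index=sorted(transcripts),
        name="occupancy_factor",
    )
    tracks: dict[str, CountTrack] = {}
    for gid in sorted(transcripts):
        t = transcripts[gid]
        rate = np.full(t.length, config.utr_rpf_rate)
        rate[t.cds_start : t.cds_end] = 1.0
        rate *= abundance[gid] * factors[gid] * config.depth_rpf / t.length
        reads = _poisson_counts(rng, rate, config.overdispersion)
        counts = {int(p): int(c) for p, c in enumerate(reads) if c > 0}
        tracks[gid] = CountTrack(gid, "rpf", counts)
    return tracks, factors


@dataclass
class RecoveryReport:
    n_planted: int
    n_recovered: int
    n_false_positives: int
    table: pd.DataFrame  # feature, beta, coefficient, recovered, sign_ok

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else 0.0


def recovery_report(fitted: FittedModel, truth: SimGroundTruth) -> RecoveryReport:
    """Which planted effects the fitted model found, and how many nonzero
    coefficients are spurious.  A planted feature counts as recovered when
    its coefficient is nonzero with the planted sign."""
    coef = dict(zip(fitted.feature_names, fitted.coef))
    rows = []
    recovered = 0
    for feat, beta in zip(truth.planted["feature"], truth.planted["beta"]):
        c = float(coef.get(feat, 0.0))
        sign_ok = c != 0.0 and np.sign(c) == np.sign(beta)
        recovered += int(sign_ok)
        rows.append(
            {
                "feature": feat,
                "beta": float(beta),
                "coefficient": c,
                "recovered": c != 0.0,
                "sign_ok": sign_ok,
                "abs_error": abs(c - beta),
            }
        )
    planted_names = set(truth.planted["feature"])
    fp = sum(
        1
        for name, c in zip(fitted.feature_names, fitted.coef)
        if c != 0.0 and name not in planted_names
    )
    return RecoveryReport(
        n_planted=len(rows),
        n_recovered=recovered,
        n_false_positives=fp,
        table=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Canned end-to-end recovery benchmark
# ---------------------------------------------------------------------------


def recovery_scenario(seed: int = 11, n_genes: int = 500):
    """Standard parameter-recovery benchmark: ~10k sites, ~240 enumerated
    features, 10 planted effects with |beta| >= 0.3 and noise sd 0.5.

    Planted around-site nucleotide zones are separated so that no enumerated
    window (max length 3) can align two same-signed effects, which would
    otherwise let an aggregate window out-correlate a planted one and knock
    it out during decorrelation.

    Returns (SimConfig, FeatureConfig).
    """
    feat_cfg = FeatureConfig(
        seq_max_offset=8,
        seq_min_len=1,
        seq_max_len=3,
        seq_step=1,
        nt_k=(1,),
        include_codon_around=False,
        include_aa_around=False,
        struct_min_len=8,
        struct_max_len=16,
        struct_step=8,
        occ_max_offset=8,
        occ_min_len=8,
        occ_max_len=16,
        occ_step=8,
        region_nt_k=(1,),
        include_region_codon=False,
        end_block_nt=20,
        end_block_codons=5,
    )
    planted = [
        (FeatureSpec("nucleotide", "around_site", window=(1, 1), token="G"), 0.5),
        (FeatureSpec("nucleotide", "around_site", window=(5, 7), token="A"), 0.35),
        (FeatureSpec("nucleotide", "around_site", window=(-7, -5), token="U"), -0.4),
        (FeatureSpec("nucleotide", "around_site", window=(-4, -3), token="C"), -0.35),
        (FeatureSpec("structure", "around_site", window=(-8, 8)), -0.3),
        (FeatureSpec("occupancy", "around_site", window=(1, 8)), 0.4),
        (FeatureSpec("occupancy", "whole_rna", region="whole"), 0.5),
        (FeatureSpec("nucleotide", "whole_rna", region="cds", token="G"), 0.3),
        (FeatureSpec("structure", "whole_rna", region="3utr"), -0.3),
        (FeatureSpec("nucleotide", "whole_rna", region="5utr", token="A"), 0.3),
    ]
    sim_cfg = SimConfig(
        n_genes=n_genes,
        seed=seed,
        site_context=8,
        site_density=0.125,
        utr5_len=(15, 40),
        cds_codons=(40, 80),
        utr3_len=(15, 50),
        planted=planted,
        alpha0=0.3,
        sigma_eps=0.5,
        depth_degradome=2.0,
    )
    return sim_cfg, feat_cfg


def run_recovery_pipeline(seed: int = 11, n_genes: int = 500):
    """Simulate, score, featurize, prune and fit the recovery benchmark.

    Returns (RecoveryReport, EvalReport, FittedModel, SimGroundTruth).
    The L1 penalty is cross-validated on a log grid wide enough for the
    paper-scale objective (lambda = 2n * sklearn alpha) to reach sparsity.
    """
    from .cleavage_scoring import (
        compute_abundance,
        compute_cs_table,
        compute_ro_table,
        split_sites,
    )
    from .feature_extraction import build_feature_matrix
    from .feature_pruning import prune
    from .penalized_models import (
        ModelConfig,
        cv_lambda,
        fit_penalized,
        predict_and_evaluate,
        select_lambda,
    )

    sim_cfg, feat_cfg = recovery_scenario(seed, n_genes)
    transcripts = simulate_transcripts(sim_cfg)
    rpf_tracks, _ = simulate_ribosome(transcripts, sim_cfg)
    ab_exp = gene_abundances(sim_cfg, sorted(transcripts))
    cap_expected = {
        g: CountTrack(
            g, "cap", {0: max(1, int(round(ab_exp[g] * sim_cfg.depth_cap)))}
        )
        for g in sorted(transcripts)
    }
    occupancy0 = compute_ro_table(
        rpf_tracks, compute_abundance(cap_expected), transcripts
    )
    deg_tracks, cap_tracks, truth = simulate_degradome(
        transcripts, sim_cfg, occupancy0, feat_cfg
    )

    abundance = compute_abundance(cap_tracks)
    cs = compute_cs_table(deg_tracks, abundance)
    cs = split_sites(cs, test_fraction=0.1, seed=seed)
    occupancy = compute_ro_table(rpf_tracks, abundance, transcripts)
    matrix = build_feature_matrix(cs, transcripts, occupancy, feat_cfg)
    pruned, _report = prune(matrix, 0.1, 0.6)

    config = ModelConfig(
        penalty="l1",
        lambda_grid=tuple(float(x) for x in np.logspace(1, 4, 13)),
        cv_folds=10,
        seed=seed,
    )
    train = pruned.rows("train")
    cv = cv_lambda(train, config)
    lam = select_lambda(cv, tolerance=0.05)
    model = fit_penalized(train, config, lam)
    evaluation = predict_and_evaluate(model, pruned.rows("test"))
    return recovery_report(model, truth), evaluation, model, truth
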