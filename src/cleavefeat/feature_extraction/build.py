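"""Feature-value computation and the feature-matrix builder.

Per-gene token occurrence profiles are cumulative-summed once, so every
window frequency is an O(1) lookup; structure windows go through the
(cached) folding backend.
"""

from __future__ import annotations

import logging
import re
from typing import Mapping

import numpy as np
import pandas as pd

from ..cleavage_scoring import CleavageSiteTable, OccupancyTable
from ..transcript_io import FeatureMatrix, Transcript
from .folding import fold_mfe, make_vienna_backend
from .specs import CODON_TO_AA, FeatureConfig, FeatureSpec, enumerate_feature_specs
from .windows import Window, window_length, window_transcript_span

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Scalar operations
# ---------------------------------------------------------------------------


def kmer_frequency(seq_window: str, token: str) -> float:
    """Overlapping-occurrence frequency of ``token`` in ``seq_window``.

    Denominator is the number of length-k slots; 0 when the window is
    shorter than the token.
    """
    if set(token) - set("ACGU") or not token:
        raise ValueError(f"invalid token {token!r}")
    k = len(token)
    n = len(seq_window)
    if n < k:
        return 0.0
    if k == 1:
        count = seq_window.count(token)
    else:  # overlapping occurrences
        count = len(re.findall(f"(?={token})", seq_window))
    return count / (n - k + 1)


def _codon_index_range(
    transcript: Transcript, a: int, b: int
) -> tuple[int, int] | None:
    """In-frame codon indices (inclusive) fully inside the CDS that overlap
    the half-open transcript span [a, b), or None."""
    n_codons = (transcript.cds_end - transcript.cds_start) // 3
    if b <= transcript.cds_start or a >= transcript.cds_end or n_codons == 0:
        return None
    c_lo = max(0, (a - transcript.cds_start) // 3)
    c_hi = min(n_codons - 1, (b - 1 - transcript.cds_start) // 3)
    if c_hi < c_lo:
        return None
    return c_lo, c_hi


def codon_aa_frequency(
    transcript: Transcript,
    token: str,
    *,
    window: Window | None = None,
    site: int | None = None,
    region: str | None = None,
    n_block: int = 10,
) -> float:
    """Codon or amino-acid frequency over in-frame CDS codons.

    For around-site use pass ``window`` and ``site``; for whole-RNA use
    pass ``region`` in {"cds", "cds_start_codons", "cds_stop_codons"}.
    Codon frequencies count all codons in the denominator; amino-acid
    frequencies exclude stop codons from the denominator.  Returns 0 when
    no in-frame codon is covered.
    """
    codons = transcript.codons()
    if window is not None:
        if site is None:
            raise ValueError("around-site codon frequency needs the site position")
        a, b = window_transcript_span(window, site)
        rng = _codon_index_range(transcript, a, b)
        if rng is None:
            return 0.0
        sel = codons[rng[0] : rng[1] + 1]
    elif region == "cds":
        sel = codons
    elif region == "cds_start_codons":
        sel = codons[:n_block]
    elif region == "cds_stop_codons":
        sel = codons[-n_block:]
    else:
        raise ValueError(f"unsupported region {region!r} for codon features")
    if not sel:
        return 0.0
    if len(token) == 3:
        return sum(1 for c in sel if c == token) / len(sel)
    aas = [CODON_TO_AA[c] for c in sel]
    denom = sum(1 for aa in aas if aa != "*")
    if denom == 0:
        return 0.0
    return sum(1 for aa in aas if aa == token) / denom


def window_ro(
    occupancy: OccupancyTable,
    gene_id: str,
    site: int,
    window: Window,
    transcript_length: int,
) -> float:
    """Mean per-site ribosome occupancy over a site window, truncated at the
    transcript bounds; 0 when no in-bounds positions remain."""
    a, b = window_transcript_span(window, site)
    a, b = max(a, 0), min(b, transcript_length)
    if b <= a:
        return 0.0
    dense = occupancy.gene_dense(gene_id, transcript_length)
    return float(dense[a:b].mean())


# ---------------------------------------------------------------------------
# Region feature values
# ---------------------------------------------------------------------------


def _region_sequence(transcript: Transcript, region: str, end_block_nt: int) -> str:
    if region.endswith("_end5") or region.endswith("_end3"):
        base, end = region.rsplit("_", 1)
        lo, hi = transcript.region_bounds(base)
        seq = transcript.seq[lo:hi]
        return seq[:end_block_nt] if end == "end5" else seq[-end_block_nt:]
    lo, hi = transcript.region_bounds(region)
    return transcript.seq[lo:hi]


def _region_value(
    spec: FeatureSpec,
    transcript: Transcript,
    ro_row: pd.Series | None,
    config: FeatureConfig,
    fold_backend,
) -> float:
    if spec.category == "occupancy":
        if ro_row is None:
            return 0.0
        return float(ro_row[f"ro_{spec.region}"])
    if spec.category in ("codon", "amino_acid"):
        return codon_aa_frequency(
            transcript, spec.token, region=spec.region, n_block=config.end_block_codons
        )
    seq = _region_sequence(transcript, spec.region, config.end_block_nt)
    if not seq:
        logger.debug("%s: empty region %s, feature set to 0", transcript.id, spec.region)
        return 0.0
    if spec.category == "structure":
        return fold_mfe(seq, backend=fold_backend)
    return kmer_frequency(seq, spec.token)


def region_features(
    transcript: Transcript,
    occupancy: OccupancyTable | None,
    config: FeatureConfig | None = None,
) -> dict[FeatureSpec, float]:
    """All whole-RNA feature values for one transcript."""
    config = config or FeatureConfig()
    specs = [s for s in enumerate_feature_specs(config) if s.scope == "whole_rna"]
    fold_backend = _resolve_fold_backend(config)
    ro_row = None
    if occupancy is not None:
        hits = occupancy.region_sums.loc[occupancy.region_sums["gene_id"] == transcript.id]
        if len(hits):
            ro_row = hits.iloc[0]
    return {
        s: _region_value(s, transcript, ro_row, config, fold_backend) for s in specs
    }


# ---------------------------------------------------------------------------
# Vectorized per-gene evaluation
# ---------------------------------------------------------------------------


def _resolve_fold_backend(config: FeatureConfig):
    if config.fold_backend == "vienna":
        return make_vienna_backend()
    if config.fold_backend == "internal":
        return None
    raise ValueError(f"unknown fold backend {config.fold_backend!r}")


def required_context(specs: list[FeatureSpec]) -> int:
    """Nucleotides of flanking sequence a site must have on each side for
    every sequence/structure window in ``specs`` to be computable."""
    m = 0
    for s in specs:
        if s.scope == "around_site" and s.category in ("nucleotide", "codon", "amino_acid", "structure"):
            m = max(m, abs(s.window[0]), abs(s.window[1]))
    return m


def _token_cumsum(seq_idx: np.ndarray, token: str) -> np.ndarray:
    """Cumulative count of overlapping occurrences of ``token`` by start
    position; entry i = number of occurrences starting before position i."""
    k = len(token)
    L = len(seq_idx)
    if L < k:
        return np.zeros(1, dtype=np.int64)
    tok_idx = np.fromiter(("ACGU".index(c) for c in token), dtype=np.intp, count=k)
    ind = np.ones(L - k + 1, dtype=bool)
    for j in range(k):
        ind &= seq_idx[j : L - k + 1 + j] == tok_idx[j]
    cs = np.zeros(L - k + 2, dtype=np.int64)
    np.cumsum(ind, out=cs[1:])
    return cs


def evaluate_specs(
    sites: pd.DataFrame,
    transcripts: Mapping[str, Transcript],
    occupancy: OccupancyTable | None,
    specs: list[FeatureSpec],
    config: FeatureConfig | None = None,
) -> np.ndarray:
    """Dense (n_sites, len(specs)) value matrix for arbitrary specs.

    ``sites`` needs ``gene_id`` and ``position`` columns, where position is
    the transcript coordinate of the detected 5' end (+1 nucleotide).
    Sequence windows must be fully inside the transcript (ValueError
    otherwise); occupancy windows are truncated at the bounds.
    """
    config = config or FeatureConfig()
    fold_backend = _resolve_fold_backend(config)

    around_nt: list[tuple[int, Window, str]] = []
    around_cod: list[tuple[int, Window, str]] = []
    around_struct: list[tuple[int, Window]] = []
    around_occ: list[tuple[int, Window]] = []
    region_specs: list[tuple[int, FeatureSpec]] = []
    for col, s in enumerate(specs):
        if s.scope == "whole_rna":
            region_specs.append((col, s))
        elif s.category == "nucleotide":
            around_nt.append((col, s.window, s.token))
        elif s.category in ("codon", "amino_acid"):
            around_cod.append((col, s.window, s.token))
        elif s.category == "structure":
            around_struct.append((col, s.window))
        else:
            around_occ.append((col, s.window))

    need_occ = bool(around_occ) or any(
        s.category == "occupancy" for _, s in region_specs
    )
    if need_occ and occupancy is None:
        raise ValueError("occupancy features requested but no occupancy table given")

    n = len(sites)
    X = np.zeros((n, len(specs)), dtype=float)
    gene_groups = sites.groupby("gene_id", sort=False).indices

    ro_by_gene: dict = {}
    region_row_by_gene: dict = {}
    if occupancy is not None:
        for gid, grp in occupancy.sites.groupby("gene_id", sort=False):
            ro_by_gene[gid] = (
                grp["position"].to_numpy(dtype=int),
                grp["ro_site"].to_numpy(dtype=float),
            )
        for _, row in occupancy.region_sums.iterrows():
            region_row_by_gene[row["gene_id"]] = row

    for gene_id, row_idx in gene_groups.items():
        if gene_id not in transcripts:
            raise KeyError(f"transcript missing for gene {gene_id}")
        t = transcripts[gene_id]
        L = t.length
        pos = sites["position"].to_numpy()[row_idx].astype(int)
        seq_idx = np.fromiter(("ACGU".index(c) for c in t.seq), dtype=np.intp, count=L)

        if around_nt:
            cumsums: dict[str, np.ndarray] = {}
            for col, win, tok in around_nt:
                k = len(tok)
                wlen = window_length(win)
                a = pos + (win[0] if win[0] < 0 else win[0] - 1)
                b = a + wlen
                if (a < 0).any() or (b > L).any():
                    raise ValueError(
                        f"sequence window {win} out of bounds for gene {gene_id}"
                    )
                if wlen < k:
                    continue
                if tok not in cumsums:
                    cumsums[tok] = _token_cumsum(seq_idx, tok)
                cs = cumsums[tok]
                X[row_idx, col] = (cs[b - k + 1] - cs[a]) / (wlen - k + 1)

        if around_cod:
            codons = np.array(t.codons(), dtype="<U3")
            nc = len(codons)
            aas = np.array([CODON_TO_AA[c] for c in codons], dtype="<U1")
            nonstop_cs = np.concatenate([[0], np.cumsum(aas != "*")])
            tok_cs: dict[str, np.ndarray] = {}
            for col, win, tok in around_cod:
                wlen = window_length(win)
                a = pos + (win[0] if win[0] < 0 else win[0] - 1)
                b = a + wlen
                c_lo = np.maximum(0, (a - t.cds_start) // 3)
                c_hi = np.minimum(nc - 1, (b - 1 - t.cds_start) // 3)
                valid = (b > t.cds_start) & (a < t.cds_end) & (c_hi >= c_lo) & (nc > 0)
                if tok not in tok_cs:
                    target = codons == tok if len(tok) == 3 else aas == tok
                    tok_cs[tok] = np.concatenate([[0], np.cumsum(target)])
                cs = tok_cs[tok]
                c_lo_s, c_hi_s = np.where(valid, c_lo, 0), np.where(valid, c_hi, 0)
                count = cs[c_hi_s + 1] - cs[c_lo_s]
                if len(tok) == 3:
                    denom = (c_hi_s - c_lo_s + 1).astype(float)
                else:
                    denom = (nonstop_cs[c_hi_s + 1] - nonstop_cs[c_lo_s]).astype(float)
                ok = valid & (denom > 0)
                X[row_idx, col] = np.where(ok, count / np.maximum(denom, 1.0), 0.0)

        for col, win in around_struct:
            wlen = window_length(win)
            a = pos + (win[0] if win[0] < 0 else win[0] - 1)
            b = a + wlen
            if (a < 0).any() or (b > L).any():
                raise ValueError(f"structure window {win} out of bounds for {gene_id}")
            vals = [fold_mfe(t.seq[ai:bi], backend=fold_backend) for ai, bi in zip(a, b)]
            X[row_idx, col] = vals

        if around_occ:
            dense = np.zeros(L)
            if gene_id in ro_by_gene:
                positions, ros = ro_by_gene[gene_id]
                dense[positions] = ros
            rocs = np.concatenate([[0.0], np.cumsum(dense)])
            for col, win in around_occ:
                wlen = window_length(win)
                a = pos + (win[0] if win[0] < 0 else win[0] - 1)
                b = a + wlen
                a2, b2 = np.clip(a, 0, L), np.clip(b, 0, L)
                span = (b2 - a2).astype(float)
                sums = rocs[b2] - rocs[a2]
                X[row_idx, col] = np.where(span > 0, sums / np.maximum(span, 1.0), 0.0)

        if region_specs:
            ro_row = region_row_by_gene.get(gene_id)
            for col, s in region_specs:
                X[row_idx, col] = _region_value(s, t, ro_row, config, fold_backend)

    return X


def build_feature_matrix(
    sites: CleavageSiteTable,
    transcripts: Mapping[str, Transcript],
    occupancy: OccupancyTable | None,
    config: FeatureConfig | None = None,
) -> FeatureMatrix:
    """One row per site with full +/- sequence context, one column per
    enumerated feature, in deterministic (category, scope, region/window,
    token) order."""
    config = config or FeatureConfig()
    specs = enumerate_feature_specs(config)

    df = sites.sites
    m = config.seq_max_offset
    lengths = df["gene_id"].map(lambda g: transcripts[g].length)
    ok = (df["position"] - m >= 0) & (df["position"] + m <= lengths)
    dropped = int((~ok).sum())
    if dropped:
        logger.info(
            "build_feature_matrix: %d/%d sites lack full +/-%d context; dropped",
            dropped,
            len(df),
            m,
        )
    kept = df.loc[ok].reset_index(drop=True)
    site_info = pd.DataFrame(
        {
            "gene_id": kept["gene_id"],
            "position": kept["position"].astype(int),
            "y": kept["cs_site"].astype(float),
            "split": kept["split"] if "split" in kept else "none",
        }
    )
    X = evaluate_specs(site_info, transcripts, occupancy, specs, config)
    return FeatureMatrix(site_info, X, specs)
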