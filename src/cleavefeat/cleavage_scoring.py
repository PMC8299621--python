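"""Cleavage-score and ribosome-occupancy tables, reliability filters, and
gene-level train/test splitting.

The site-level cleavage score at a position is the degradome 5'-end read
count there divided by the gene's capped-read total; the gene-level score is
the sum of its site scores.  Ribosome occupancy is the analogous ratio for
ribosome-protected-fragment reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .transcript_io import CountTrack, Transcript

logger = logging.getLogger(__name__)

DEFAULT_MIN_CAP_READS = 50
DEFAULT_MIN_CLEAVED_FRAC = 0.20
DEFAULT_PERCENTILE_BAND = (5.0, 95.0)


@dataclass
class AbundanceTable:
    """Per-gene capped-read totals with a retention flag.

    A gene is retained when its cap-read total is strictly greater than
    ``min_cap_reads`` (default 50).
    """

    table: pd.DataFrame  # columns: gene_id, cap_total, retained
    min_cap_reads: int = DEFAULT_MIN_CAP_READS

    def abundance(self, gene_id: str) -> int:
        row = self.table.loc[self.table["gene_id"] == gene_id]
        if len(row) == 0:
            raise KeyError(gene_id)
        return int(row["cap_total"].iloc[0])

    @property
    def retained_genes(self) -> list[str]:
        return self.table.loc[self.table["retained"], "gene_id"].tolist()

    def as_mapping(self) -> dict[str, int]:
        return dict(zip(self.table["gene_id"], self.table["cap_total"]))


@dataclass
class CleavageSiteTable:
    """Per-site cleavage scores plus per-gene totals.

    ``sites`` has columns ``gene_id``, ``position``, ``reads``, ``cs_site``
    and ``split`` (one of ``train``/``test``/``none``).
    """

    sites: pd.DataFrame

    @property
    def cs_gene(self) -> pd.Series:
        return self.sites.groupby("gene_id", sort=True)["cs_site"].sum()

    @property
    def genes(self) -> list[str]:
        return sorted(self.sites["gene_id"].unique())

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class OccupancyTable:
    """Per-site ribosome occupancy plus per-gene and per-region sums."""

    sites: pd.DataFrame  # columns: gene_id, position, ro_site
    region_sums: pd.DataFrame  # gene_id, ro_5utr, ro_cds, ro_3utr, ro_whole

    @property
    def ro_gene(self) -> pd.Series:
        return self.sites.groupby("gene_id", sort=True)["ro_site"].sum()

    def gene_sparse(self, gene_id: str) -> pd.DataFrame:
        return self.sites.loc[self.sites["gene_id"] == gene_id]

    def gene_dense(self, gene_id: str, length: int) -> np.ndarray:
        arr = np.zeros(length, dtype=float)
        sub = self.gene_sparse(gene_id)
        arr[sub["position"].to_numpy(dtype=int)] = sub["ro_site"].to_numpy()
        return arr


def compute_abundance(
    cap_tracks: Mapping[str, CountTrack] | list[CountTrack],
    min_cap_reads: int = DEFAULT_MIN_CAP_READS,
) -> AbundanceTable:
    """Sum cap-read counts per gene and flag genes above the read threshold."""
    tracks = list(cap_tracks.values()) if isinstance(cap_tracks, Mapping) else list(cap_tracks)
    for tr in tracks:
        if tr.kind != "cap":
            raise ValueError(f"expected cap track, got {tr.kind!r} for {tr.transcript_id}")
    rows = [(tr.transcript_id, tr.total) for tr in tracks]
    rows.sort()
    df = pd.DataFrame(rows, columns=["gene_id", "cap_total"])
    df["retained"] = df["cap_total"] > min_cap_reads
    return AbundanceTable(df, min_cap_reads)


def compute_cs_table(
    degradome_tracks: Mapping[str, CountTrack] | list[CountTrack],
    abundance: AbundanceTable,
) -> CleavageSiteTable:
    """Score every degradome position of every retained gene.

    cs_site = degradome reads at the position / gene cap-read total.
    Positions with zero reads are not represented (sparse).  Tracks for
    genes not retained in the abundance table are dropped with a logged
    count.
    """
    tracks = (
        list(degradome_tracks.values())
        if isinstance(degradome_tracks, Mapping)
        else list(degradome_tracks)
    )
    totals = abundance.as_mapping()
    retained = set(abundance.retained_genes)
    rows = []
    n_dropped = 0
    for tr in tracks:
        if tr.kind != "degradome":
            raise ValueError(f"expected degradome track, got {tr.kind!r}")
        if tr.transcript_id not in retained:
            n_dropped += 1
            continue
        total = totals[tr.transcript_id]
        for pos in sorted(tr.counts):
            reads = tr.counts[pos]
            if reads > 0:
                rows.append((tr.transcript_id, pos, reads, reads / total))
    if n_dropped:
        logger.info("compute_cs_table: %d tracks for non-retained genes dropped", n_dropped)
    df = pd.DataFrame(rows, columns=["gene_id", "position", "reads", "cs_site"])
    df["split"] = "none"
    df = df.sort_values(["gene_id", "position"]).reset_index(drop=True)
    return CleavageSiteTable(df)


def compute_ro_table(
    rpf_tracks: Mapping[str, CountTrack] | list[CountTrack],
    abundance: AbundanceTable,
    transcripts: Mapping[str, Transcript],
) -> OccupancyTable:
    """Normalize RPF 5'-end counts to abundance and sum per region."""
    tracks = (
        list(rpf_tracks.values()) if isinstance(rpf_tracks, Mapping) else list(rpf_tracks)
    )
    totals = abundance.as_mapping()
    retained = set(abundance.retained_genes)
    rows = []
    region_rows = []
    n_dropped = 0
    for tr in tracks:
        if tr.kind != "rpf":
            raise ValueError(f"expected rpf track, got {tr.kind!r}")
        gid = tr.transcript_id
        if gid not in retained:
            n_dropped += 1
            continue
        total = totals[gid]
        sums = {"5utr": 0.0, "cds": 0.0, "3utr": 0.0}
        t = transcripts.get(gid)
        for pos in sorted(tr.counts):
            if tr.counts[pos] <= 0:
                continue
            ro = tr.counts[pos] / total
            rows.append((gid, pos, ro))
            if t is not None:
                if pos < t.cds_start:
                    sums["5utr"] += ro
                elif pos < t.cds_end:
                    sums["cds"] += ro
                else:
                    sums["3utr"] += ro
        region_rows.append(
            (gid, sums["5utr"], sums["cds"], sums["3utr"], sum(sums.values()))
        )
    if n_dropped:
        logger.info("compute_ro_table: %d tracks for non-retained genes dropped", n_dropped)
    sites = pd.DataFrame(rows, columns=["gene_id", "position", "ro_site"])
    sites = sites.sort_values(["gene_id", "position"]).reset_index(drop=True)
    region_sums = pd.DataFrame(
        sorted(region_rows),
        columns=["gene_id", "ro_5utr", "ro_cds", "ro_3utr", "ro_whole"],
    )
    return OccupancyTable(sites, region_sums)


def filter_reliable_sites(
    cs: CleavageSiteTable,
    transcripts: Mapping[str, Transcript],
    exclusion: pd.DataFrame | None = None,
    min_cleaved_frac: float = DEFAULT_MIN_CLEAVED_FRAC,
    percentile_band: tuple[float, float] | None = DEFAULT_PERCENTILE_BAND,
) -> CleavageSiteTable:
    """Keep sites of genes passing both reliability rules.

    A gene passes when (a) the fraction of its positions carrying at least
    one degradome read exceeds ``min_cleaved_frac`` of the transcript
    length, and (b) its gene-level score lies strictly between the stated
    percentiles of the gene-level scores of the genes surviving rule (a).
    Percentiles use linear interpolation; ``percentile_band=None`` disables
    rule (b).  Finally any (gene, position) pair present in ``exclusion``
    (columns gene_id, position) is dropped.
    """
    df = cs.sites
    if len(df) == 0:
        return CleavageSiteTable(df.copy())
    for gid in df["gene_id"].unique():
        if gid not in transcripts:
            raise KeyError(f"transcript missing for gene {gid}")

    cleaved = df.groupby("gene_id")["position"].nunique()
    lengths = pd.Series({g: transcripts[g].length for g in cleaved.index})
    frac_pass = cleaved / lengths > min_cleaved_frac
    genes_a = set(frac_pass.index[frac_pass])

    sub = df[df["gene_id"].isin(genes_a)]
    if percentile_band is None:
        genes_b = genes_a
    else:
        cs_gene = sub.groupby("gene_id")["cs_site"].sum()
        lo, hi = np.percentile(cs_gene.to_numpy(), percentile_band)
        genes_b = set(cs_gene.index[(cs_gene > lo) & (cs_gene < hi)])

    out = df[df["gene_id"].isin(genes_b)].copy()
    if exclusion is not None and len(exclusion):
        excl = set(zip(exclusion["gene_id"].astype(str), exclusion["position"].astype(int)))
        keep = [
            (g, int(p)) not in excl
            for g, p in zip(out["gene_id"], out["position"])
        ]
        out = out[keep]
    n_dropped = len(df) - len(out)
    logger.info(
        "filter_reliable_sites: kept %d/%d sites (%d genes)",
        len(out),
        len(df),
        out["gene_id"].nunique(),
    )
    if n_dropped < 0:  # pragma: no cover - defensive
        raise AssertionError
    return CleavageSiteTable(out.reset_index(drop=True))


def split_sites(
    cs: CleavageSiteTable, test_fraction: float = 0.1, seed: int = 0
) -> CleavageSiteTable:
    """Randomly partition genes into train/test; sites inherit gene labels.

    The split is at gene level so that sites of one gene never straddle the
    partition, and is deterministic given the seed.
    """
    genes = sorted(cs.sites["gene_id"].unique())
    if len(genes) < 10:
        raise ValueError(f"need at least 10 genes to split, got {len(genes)}")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    n_test = int(round(len(genes) * test_fraction))
    n_test = min(max(n_test, 1), len(genes) - 1)
    test_genes = {genes[i] for i in order[:n_test]}
    df = cs.sites.copy()
    df["split"] = np.where(df["gene_id"].isin(test_genes), "test", "train")
    return CleavageSiteTable(df)
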