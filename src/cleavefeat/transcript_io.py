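"""Readers and writers for transcripts, count tracks, feature matrices and
model reports.

Conventions
-----------
* All coordinates are 0-based, half-open, on spliced-transcript coordinates.
* DNA input is accepted: ``T`` is mapped to ``U`` on read; every internal
  sequence is over the alphabet ``{A, C, G, U}``.
* Count tracks are sparse: only positions with at least one read are stored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .feature_extraction import FeatureSpec

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
TRACK_KINDS = ("degradome", "cap", "rpf")

STOP_CODONS = ("UAA", "UAG", "UGA")


class TranscriptError(ValueError):
    """Raised for malformed transcript or track input."""


@dataclass(frozen=True)
class Transcript:
    """A spliced transcript with CDS coordinates.

    ``cds_start`` is the 0-based index of the first CDS nucleotide and
    ``cds_end`` is one past the last nucleotide of the stop codon.
    """

    id: str
    seq: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= len(self.seq)):
            raise TranscriptError(
                f"{self.id}: CDS [{self.cds_start}, {self.cds_end}) outside "
                f"sequence of length {len(self.seq)}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise TranscriptError(
                f"{self.id}: CDS length {self.cds_end - self.cds_start} "
                "not divisible by 3"
            )
        bad = set(self.seq) - RNA_ALPHABET
        if bad:
            raise TranscriptError(f"{self.id}: invalid symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def utr5(self) -> str:
        return self.seq[: self.cds_start]

    @property
    def cds(self) -> str:
        return self.seq[self.cds_start : self.cds_end]

    @property
    def utr3(self) -> str:
        return self.seq[self.cds_end :]

    def region_bounds(self, region: str) -> tuple[int, int]:
        """Half-open transcript-coordinate bounds of a named region."""
        if region == "5utr":
            return 0, self.cds_start
        if region == "cds":
            return self.cds_start, self.cds_end
        if region == "3utr":
            return self.cds_end, self.length
        if region == "whole":
            return 0, self.length
        raise ValueError(f"unknown region {region!r}")

    def codons(self) -> list[str]:
        c = self.cds
        return [c[i : i + 3] for i in range(0, len(c), 3)]


@dataclass(frozen=True)
class CountTrack:
    """Sparse per-position 5'-end read counts for one transcript."""

    transcript_id: str
    kind: str
    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")
        for pos, c in self.counts.items():
            if pos < 0:
                raise TranscriptError(
                    f"{self.transcript_id}: negative position {pos}"
                )
            if c < 0:
                raise TranscriptError(
                    f"{self.transcript_id}: negative count {c} at {pos}"
                )

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def dense(self, length: int) -> np.ndarray:
        arr = np.zeros(length, dtype=float)
        for pos, c in self.counts.items():
            arr[pos] = c
        return arr


def _clean_seq(raw: str) -> str:
    return str(raw).upper().replace("T", "U")


def read_transcripts(
    fasta_path: str | Path, region_table_path: str | Path
) -> dict[str, Transcript]:
    """Load transcripts from a FASTA file plus a 3-column region TSV.

    The region table has columns ``id``, ``cds_start``, ``cds_end``
    (0-based, half-open).  Records failing validation (bad alphabet, CDS
    length not divisible by 3, id missing from the FASTA) are skipped and
    counted in the log rather than raising.
    """
    fasta_path, region_table_path = Path(fasta_path), Path(region_table_path)
    seqs = {rec.id: _clean_seq(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    regions = pd.read_csv(
        region_table_path,
        sep="\t",
        comment="#",
        names=["id", "cds_start", "cds_end"],
        header=None,
        dtype={"id": str},
    )
    # tolerate a header row
    if len(regions) and str(regions.iloc[0, 0]).lower() in ("id", "transcript_id"):
        regions = regions.iloc[1:].reset_index(drop=True)
    regions["cds_start"] = regions["cds_start"].astype(int)
    regions["cds_end"] = regions["cds_end"].astype(int)

    out: dict[str, Transcript] = {}
    n_skipped = 0
    for row in regions.itertuples(index=False):
        if row.id not in seqs:
            logger.warning("region id %s absent from FASTA; skipped", row.id)
            n_skipped += 1
            continue
        try:
            out[row.id] = Transcript(row.id, seqs[row.id], row.cds_start, row.cds_end)
        except TranscriptError as exc:
            logger.warning("skipping %s: %s", row.id, exc)
            n_skipped += 1
    if n_skipped:
        logger.info("read_transcripts: %d records skipped", n_skipped)
    return out


def read_count_track(
    path: str | Path,
    kind: str,
    transcripts: Mapping[str, Transcript] | None = None,
) -> dict[str, CountTrack]:
    """Read a bedGraph-like TSV (transcript_id, position, count).

    Duplicate (id, position) rows are summed.  Negative counts or positions
    are a hard error; out-of-range positions are a hard error when
    ``transcripts`` is supplied for validation.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            names=["transcript_id", "position", "count"],
            header=None,
            dtype={"transcript_id": str},
        )
    except pd.errors.EmptyDataError:
        return {}
    if len(df) == 0:
        return {}
    df["position"] = df["position"].astype(int)
    df["count"] = df["count"].astype(int)
    if (df["count"] < 0).any():
        raise TranscriptError(f"{path}: negative count")
    if (df["position"] < 0).any():
        raise TranscriptError(f"{path}: negative position")
    summed = df.groupby(["transcript_id", "position"], sort=True)["count"].sum()
    tracks: dict[str, CountTrack] = {}
    for tid, grp in summed.groupby(level=0):
        counts = {int(pos): int(c) for (_, pos), c in grp.items()}
        if transcripts is not None and tid in transcripts:
            length = transcripts[tid].length
            bad = [p for p in counts if p >= length]
            if bad:
                raise TranscriptError(
                    f"{path}: position {bad[0]} >= length {length} for {tid}"
                )
        tracks[tid] = CountTrack(tid, kind, counts)
    return tracks


def write_count_track(tracks: Iterable[CountTrack], path: str | Path) -> None:
    """Write tracks as a sorted 3-column TSV."""
    rows = []
    for tr in tracks:
        for pos in sorted(tr.counts):
            if tr.counts[pos] > 0:
                rows.append((tr.transcript_id, pos, tr.counts[pos]))
    rows.sort()
    with open(path, "w") as fh:
        for tid, pos, c in rows:
            fh.write(f"{tid}\t{pos}\t{c}\n")


def write_transcripts(
    transcripts: Mapping[str, Transcript],
    fasta_path: str | Path,
    region_table_path: str | Path,
) -> None:
    with open(fasta_path, "w") as fh:
        for tid in sorted(transcripts):
            fh.write(f">{tid}\n{transcripts[tid].seq}\n")
    with open(region_table_path, "w") as fh:
        for tid in sorted(transcripts):
            t = transcripts[tid]
            fh.write(f"{tid}\t{t.cds_start}\t{t.cds_end}\n")


# ---------------------------------------------------------------------------
# Feature matrix persistence
# ---------------------------------------------------------------------------

_SITE_COLUMNS = ["gene_id", "position", "y", "split"]


@dataclass
class FeatureMatrix:
    """Sites-by-features matrix with per-feature metadata.

    ``site_info`` has columns ``gene_id``, ``position``, ``y`` (the
    objective, i.e. the site-level cleavage score) and ``split``
    (``train``/``test``/``none``).  ``X`` is a dense ``(n_sites, p)``
    float array; ``specs`` describe its columns in order.
    """

    site_info: pd.DataFrame
    X: np.ndarray
    specs: list["FeatureSpec"] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != len(self.site_info):
            raise ValueError("row count mismatch between X and site_info")
        if self.X.shape[1] != len(self.specs):
            raise ValueError("column count mismatch between X and specs")
        if len(self.site_info) and not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_sites(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def y(self) -> np.ndarray:
        return self.site_info["y"].to_numpy(dtype=float)

    def rows(self, split: str) -> "FeatureMatrix":
        mask = (self.site_info["split"] == split).to_numpy()
        return FeatureMatrix(
            self.site_info.loc[mask].reset_index(drop=True),
            self.X[mask],
            list(self.specs),
        )

    def select_features(self, keep: np.ndarray | list[int]) -> "FeatureMatrix":
        idx = np.asarray(keep, dtype=int)
        return FeatureMatrix(
            self.site_info.copy(), self.X[:, idx], [self.specs[i] for i in idx]
        )

    def to_tsv(self, path: str | Path) -> None:
        from .feature_extraction import FeatureSpec  # noqa: F401 - format owner

        with open(path, "w") as fh:
            for spec in self.specs:
                fh.write("#feature\t" + spec.to_header_line() + "\n")
            header = _SITE_COLUMNS + self.feature_names
            fh.write("\t".join(header) + "\n")
            for i in range(self.n_sites):
                row = self.site_info.iloc[i]
                vals = "\t".join("%.17g" % v for v in self.X[i])
                prefix = f"{row.gene_id}\t{int(row.position)}\t{row.y:.17g}\t{row.split}"
                fh.write(prefix + ("\t" + vals if vals else "") + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        from .feature_extraction import FeatureSpec

        specs: list[FeatureSpec] = []
        header: list[str] | None = None
        data_rows: list[list[str]] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#feature\t"):
                    specs.append(FeatureSpec.from_header_line(line[len("#feature\t") :]))
                elif header is None:
                    header = line.split("\t")
                else:
                    data_rows.append(line.split("\t"))
        if header is None:
            raise ValueError(f"{path}: missing header row")
        expected = _SITE_COLUMNS + [s.name for s in specs]
        if header != expected:
            raise ValueError(f"{path}: header does not match feature metadata")
        n = len(data_rows)
        site = pd.DataFrame(
            {
                "gene_id": [r[0] for r in data_rows],
                "position": [int(r[1]) for r in data_rows],
                "y": [float(r[2]) for r in data_rows],
                "split": [r[3] for r in data_rows],
            }
        )
        X = np.array(
            [[float(v) for v in r[4:]] for r in data_rows], dtype=float
        ).reshape(n, len(specs))
        return cls(site, X, specs)


# ---------------------------------------------------------------------------
# Model reports
# ---------------------------------------------------------------------------


def write_model_report(model, eval_report, path: str | Path) -> None:
    """Serialize a fitted model plus evaluation metrics as JSON.

    Nonzero coefficients are listed sorted by value, descending.
    """
    if getattr(model, "coef", None) is None:
        raise ValueError("model is not fitted")
    coefs = [
        {"feature": name, "coefficient": float(c)}
        for name, c in zip(model.feature_names, model.coef)
        if c != 0.0
    ]
    coefs.sort(key=lambda d: -d["coefficient"])
    payload = {
        "penalty": model.penalty,
        "lambda": model.lam,
        "intercept": float(model.intercept),
        "n_features": len(model.feature_names),
        "n_nonzero": len(coefs),
        "y_transform": model.y_transform,
        "coefficients": coefs,
        "evaluation": None
        if eval_report is None
        else {
            "mse": eval_report.mse,
            "pearson_r": eval_report.r,
            "r_defined": eval_report.r_defined,
            "n_sites": eval_report.n,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_model_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
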