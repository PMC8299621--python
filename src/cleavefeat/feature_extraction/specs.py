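"""Feature descriptors and the configuration governing the feature space."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml
from Bio.Seq import Seq

from .windows import Window, enumerate_site_windows, window_length

CATEGORIES = ("nucleotide", "codon", "amino_acid", "structure", "occupancy")
SCOPES = ("around_site", "whole_rna")
BASE_REGIONS = ("5utr", "cds", "3utr", "whole")
REGIONS = BASE_REGIONS + tuple(
    f"{r}_{end}" for r in BASE_REGIONS for end in ("end5", "end3")
) + ("cds_start_codons", "cds_stop_codons")

NUCLEOTIDES = ("A", "C", "G", "U")
DINUCLEOTIDES = tuple("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=2))
CODONS = tuple("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))
AMINO_ACIDS = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))

CODON_TO_AA = {c: str(Seq(c.replace("U", "T")).translate()) for c in CODONS}


def _fmt_offset(o: int) -> str:
    return f"+{o}" if o > 0 else str(o)


@dataclass(frozen=True)
class FeatureSpec:
    """Identity and placement of one explanatory variable."""

    category: str
    scope: str
    region: str = ""
    window: Window | None = None
    token: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.scope == "around_site":
            if self.window is None:
                raise ValueError("around_site feature needs a window")
            window_length(self.window)  # validates shape
        else:
            if self.region not in REGIONS:
                raise ValueError(f"unknown region {self.region!r}")
        if self.category == "nucleotide":
            if not self.token or set(self.token) - set(NUCLEOTIDES):
                raise ValueError(f"bad nucleotide token {self.token!r}")
        elif self.category == "codon":
            if self.token not in CODONS:
                raise ValueError(f"bad codon token {self.token!r}")
        elif self.category == "amino_acid":
            if self.token not in AMINO_ACIDS:
                raise ValueError(f"bad amino-acid token {self.token!r}")
        elif self.token:
            raise ValueError(f"{self.category} features carry no token")

    @property
    def name(self) -> str:
        if self.scope == "around_site":
            loc = f"{_fmt_offset(self.window[0])}..{_fmt_offset(self.window[1])}"
        else:
            loc = self.region
        parts = [self.category, self.scope, loc]
        if self.token:
            parts.append(self.token)
        return "|".join(parts)

    def sort_key(self) -> tuple:
        win = self.window if self.window is not None else (0, 0)
        return (self.category, self.scope, self.region, win, self.token)

    # --- persistence (used by the feature-matrix TSV header) ---

    def to_header_line(self) -> str:
        ws = str(self.window[0]) if self.window else "."
        we = str(self.window[1]) if self.window else "."
        return "\t".join(
            [
                self.name,
                self.category,
                self.scope,
                self.region or ".",
                ws,
                we,
                self.token or ".",
            ]
        )

    @classmethod
    def from_header_line(cls, line: str) -> "FeatureSpec":
        fields = line.split("\t")
        if len(fields) != 7:
            raise ValueError(f"malformed feature header: {line!r}")
        name, category, scope, region, ws, we, token = fields
        window = None if ws == "." else (int(ws), int(we))
        spec = cls(
            category=category,
            scope=scope,
            region="" if region == "." else region,
            window=window,
            token="" if token == "." else token,
        )
        if spec.name != name:
            raise ValueError(f"feature header name mismatch: {name!r} vs {spec.name!r}")
        return spec


@dataclass
class FeatureConfig:
    """Parameters of the enumerated feature space.

    The defaults reproduce the exhaustive space: +/-30 sequence windows of
    lengths 1-60 shifted by one nucleotide, structure windows of lengths
    5-60 shifted by five, occupancy windows over +/-200, and whole-RNA
    region features including 50-nt end blocks and 10-codon CDS end blocks.
    Shrink them for toy or simulation runs.
    """

    seq_max_offset: int = 30
    seq_min_len: int = 1
    seq_max_len: int = 60
    seq_step: int = 1
    nt_k: tuple[int, ...] = (1, 2)
    include_codon_around: bool = True
    include_aa_around: bool = True

    include_structure: bool = True
    struct_min_len: int = 5
    struct_max_len: int = 60
    struct_step: int = 5

    include_occupancy: bool = True
    occ_max_offset: int = 200
    occ_min_len: int = 1
    occ_max_len: int = 60
    occ_step: int = 1

    include_region: bool = True
    region_nt_k: tuple[int, ...] = (1, 2)
    include_region_structure: bool = True
    include_region_occupancy: bool = True
    include_region_codon: bool = True
    end_block_nt: int = 50
    end_block_codons: int = 10

    fold_backend: str = "internal"  # or "vienna"
    sequence_only: bool = False

    def __post_init__(self) -> None:
        self.nt_k = tuple(self.nt_k)
        self.region_nt_k = tuple(self.region_nt_k)

    @property
    def structure_enabled(self) -> bool:
        return self.include_structure and not self.sequence_only

    @property
    def occupancy_enabled(self) -> bool:
        return self.include_occupancy and not self.sequence_only

    @classmethod
    def toy(cls, **overrides) -> "FeatureConfig":
        """A small space suitable for tests and simulations."""
        base = dict(
            seq_max_offset=4,
            seq_min_len=1,
            seq_max_len=8,
            seq_step=1,
            nt_k=(1,),
            include_codon_around=False,
            include_aa_around=False,
            struct_min_len=4,
            struct_max_len=8,
            struct_step=4,
            occ_max_offset=8,
            occ_min_len=4,
            occ_max_len=8,
            occ_step=4,
            region_nt_k=(1,),
            include_region_codon=False,
            end_block_nt=20,
            end_block_codons=5,
        )
        base.update(overrides)
        return cls(**base)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("nt_k", "region_nt_k"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _nt_tokens(ks: tuple[int, ...]) -> list[str]:
    toks: list[str] = []
    for k in sorted(ks):
        if k == 1:
            toks.extend(NUCLEOTIDES)
        elif k == 2:
            toks.extend(DINUCLEOTIDES)
        else:
            toks.extend("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=k))
    return toks


def enumerate_feature_specs(config: FeatureConfig) -> list[FeatureSpec]:
    """The full, deterministically ordered feature space for ``config``.

    Order: sorted by (category, scope, region, window, token).
    """
    specs: list[FeatureSpec] = []

    seq_windows = enumerate_site_windows(
        config.seq_max_offset, config.seq_min_len, config.seq_max_len, config.seq_step
    )
    for win in seq_windows:
        for tok in _nt_tokens(config.nt_k):
            specs.append(FeatureSpec("nucleotide", "around_site", window=win, token=tok))
        if config.include_codon_around:
            for tok in CODONS:
                specs.append(FeatureSpec("codon", "around_site", window=win, token=tok))
        if config.include_aa_around:
            for tok in AMINO_ACIDS:
                specs.append(
                    FeatureSpec("amino_acid", "around_site", window=win, token=tok)
                )

    if config.structure_enabled:
        for win in enumerate_site_windows(
            config.seq_max_offset,
            config.struct_min_len,
            config.struct_max_len,
            config.struct_step,
        ):
            specs.append(FeatureSpec("structure", "around_site", window=win))

    if config.occupancy_enabled:
        for win in enumerate_site_windows(
            config.occ_max_offset, config.occ_min_len, config.occ_max_len, config.occ_step
        ):
            specs.append(FeatureSpec("occupancy", "around_site", window=win))

    if config.include_region:
        for region in BASE_REGIONS:
            for tok in _nt_tokens(config.region_nt_k):
                specs.append(FeatureSpec("nucleotide", "whole_rna", region=region, token=tok))
                for end in ("end5", "end3"):
                    specs.append(
                        FeatureSpec(
                            "nucleotide", "whole_rna", region=f"{region}_{end}", token=tok
                        )
                    )
            if config.include_region_structure and not config.sequence_only:
                specs.append(FeatureSpec("structure", "whole_rna", region=region))
            if config.include_region_occupancy and not config.sequence_only:
                specs.append(FeatureSpec("occupancy", "whole_rna", region=region))
        if config.include_region_codon:
            for region in ("cds", "cds_start_codons", "cds_stop_codons"):
                for tok in CODONS:
                    specs.append(FeatureSpec("codon", "whole_rna", region=region, token=tok))
                for tok in AMINO_ACIDS:
                    specs.append(
                        FeatureSpec("amino_acid", "whole_rna", region=region, token=tok)
                    )

    specs.sort(key=lambda s: s.sort_key())
    return specs
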