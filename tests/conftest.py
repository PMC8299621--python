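import numpy as np
import pandas as pd
import pytest

from cleavefeat.transcript_io import CountTrack, Transcript


@pytest.fixture
def toy_transcript() -> Transcript:
    # 5'UTR "AA", CDS "AUG GCU UAA", 3'UTR "GG"
    return Transcript("g1", "AAAUGGCUUAAGG", 2, 11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_transcript(gid: str, utr5: str, cds: str, utr3: str) -> Transcript:
    return Transcript(gid, utr5 + cds + utr3, len(utr5), len(utr5) + len(cds))


def make_track(gid: str, kind: str, counts: dict) -> CountTrack:
    return CountTrack(gid, kind, counts)


@pytest.fixture
def cap_tracks():
    return {
        "g1": make_track("g1", "cap", {0: 100}),
        "g2": make_track("g2", "cap", {0: 51}),
        "g3": make_track("g3", "cap", {0: 50}),
    }


def sites_frame(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "position", "reads", "cs_site"])
    df["split"] = "none"
    return df
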