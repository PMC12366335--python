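"""Shared helpers: seeded substreams, TSV round-tripping, checksums."""

from __future__ import annotations

import hashlib
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

#: float format that round-trips IEEE doubles through text exactly
FLOAT_FMT = "%.17g"


def substream(seed: int, name: str) -> np.random.Generator:
    """Derive a named, independent random generator from a root seed.

    The substream key is a CRC32 of the stage name, so every module gets a
    reproducible stream of its own and inserting a new stage does not shift
    the streams of existing ones.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def child_seed(seed: int, name: str) -> int:
    """A plain integer seed (< 2**31) derived from a root seed and a name."""
    key = zlib.crc32(name.encode("utf-8"))
    return int(np.random.SeedSequence([int(seed), key]).generate_state(1)[0] % (2**31))


def write_tsv(df: pd.DataFrame, path: Path | str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_tsv(path: Path | str, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def sha256_of(path: Path | str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
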