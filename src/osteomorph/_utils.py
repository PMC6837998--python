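"""Internal helpers: deterministic stage seeding and file checksums."""

from __future__ import annotations

import hashlib
import zlib
from pathlib import Path

import numpy as np


def stage_seed(root_seed: int, stage: str) -> np.random.SeedSequence:
    """Seed for a named pipeline stage, derived from one root seed.

    Stage seeds are independent of each other and of stage ordering, so
    adding a stage never perturbs the randomness of existing ones.
    """
    return np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])


def stage_rng(root_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(root_seed, stage))


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
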