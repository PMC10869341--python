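"""Deterministic per-site, per-stage random streams.

Every stochastic operation in the pipeline draws from a Generator obtained
here.  Sub-seeds are derived from the master seed by a stable, documented
rule — ``SeedSequence([master, crc32(stage), crc32(site_id)])`` — so that a
run is bit-reproducible under a fixed master seed, adding or removing sites
does not perturb the streams of other sites, and no two (stage, site) pairs
share a stream.
"""

from __future__ import annotations

import zlib

import numpy as np


def _tag(text: str) -> int:
    return zlib.crc32(text.encode("utf-8"))


def subseed(master_seed: int, stage: str, site_id: str = "") -> np.random.SeedSequence:
    """Seed sequence for one (stage, site) pair under a master seed."""
    return np.random.SeedSequence([int(master_seed), _tag(stage), _tag(site_id)])


def generator(master_seed: int, stage: str, site_id: str = "") -> np.random.Generator:
    """A PCG64 Generator keyed to (master seed, stage, site)."""
    return np.random.default_rng(subseed(master_seed, stage, site_id))
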