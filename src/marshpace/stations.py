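"""Per-site monitoring-station metadata.

Each wetland monitoring site pairs a water-level gauge anchored a few metres
below the marsh surface with a rod surface-elevation table (RSET) driven to
roughly 20 m depth.  Whether either instrument reaches the compaction-free
Pleistocene basement — i.e. whether its anchoring depth exceeds the local
Holocene–Pleistocene interface depth — decides whether a differential
vertical-land-motion correction is needed (:mod:`marshpace.vlm`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: fallback RSET rod depth (m) when the installation record is missing
DEFAULT_RSET_DEPTH_M = 20.0


@dataclass
class StationRecord:
    """Metadata for one monitoring site.

    Depths are in metres below the local wetland surface; ``tidal_amplitude``
    is the annual tidal range in metres; ``organic_fraction`` is the
    organic-matter content of the upper soil column in [0, 1].
    """

    site_id: str
    lon: float = 0.0
    lat: float = 0.0
    rset_depth: float = DEFAULT_RSET_DEPTH_M
    gauge_depth: float = 4.5
    hp_depth: float = math.nan
    survey_year: int = 2014
    tidal_amplitude: float = 0.3
    organic_fraction: float = field(default=math.nan)

    def __post_init__(self) -> None:
        for name in ("rset_depth", "gauge_depth"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{self.site_id}: {name} must be positive, got {v}")
        if not math.isnan(self.hp_depth) and self.hp_depth <= 0:
            raise ValueError(f"{self.site_id}: hp_depth must be positive")
        if self.tidal_amplitude < 0:
            raise ValueError(f"{self.site_id}: tidal_amplitude must be >= 0")
        if not math.isnan(self.organic_fraction) and not 0 <= self.organic_fraction <= 1:
            raise ValueError(f"{self.site_id}: organic_fraction outside [0, 1]")
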