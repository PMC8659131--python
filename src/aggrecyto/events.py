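"""Per-event multi-channel image container.

An imaging flow cytometer captures one small multi-channel image per
"event" (a single cell, a cell aggregate, or debris passing the camera).
The channel layout mirrors a FlowSight-class instrument:

* ``Ch01`` — brightfield (BF): bright background, absorbing cells.
* ``Ch02`` — green fluorescence (RedoxSensor Green, metabolic activity).
* ``Ch05`` — red fluorescence (propidium iodide, membrane damage).
* ``Ch06`` — darkfield / side scatter (SSC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Channel identifiers in canonical (storage) order.
CHANNELS: tuple[str, ...] = ("Ch01", "Ch02", "Ch05", "Ch06")

#: Human-oriented aliases used in feature names.
CHANNEL_ALIASES: dict[str, str] = {
    "Ch01": "BF",
    "Ch02": "Ch02",
    "Ch05": "Ch05",
    "Ch06": "SSC",
}

#: Detector saturation level (10-bit camera counts).
MAX_COUNTS = 1023


@dataclass
class EventImageSet:
    """Aligned multi-channel pixel data for a single event.

    Parameters
    ----------
    event_id:
        Unique identifier within a sample.
    channels:
        Mapping from channel id (``Ch01``, ``Ch02``, ``Ch05``, ``Ch06``)
        to a 2-D ``uint16`` array. All arrays share one shape.
    pixel_scale_um:
        Physical size of one pixel edge in micrometres.
    """

    event_id: str
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    pixel_scale_um: float = 1.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("EventImageSet requires at least one channel")
        shapes = {ch: im.shape for ch, im in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel images must share one shape, got {shapes}")
        if self.pixel_scale_um <= 0:
            raise ValueError("pixel_scale_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.channels[channel]
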