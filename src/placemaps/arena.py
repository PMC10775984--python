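"""Arena geometry for open-field recordings.

All spatial quantities in this package are expressed in millimetres with the
arena's lower-left corner at (0, 0); time is in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ArenaSpec:
    """A rectangular open-field arena.

    Parameters
    ----------
    width, height : float
        Arena extent in mm. Default is a 1.2 m x 1.2 m square box.
    grid_resolution : float
        Pixel size (mm) of the occupancy / spike-probability grids used by the
        simulators. Default 5 mm (0.5 cm).
    sample_rate : float
        Positional sampling rate in Hz. Default 50 Hz.
    """

    width: float = 1200.0
    height: float = 1200.0
    grid_resolution: float = 5.0
    sample_rate: float = 50.0

    def __post_init__(self) -> None:
        for name in ("width", "height", "grid_resolution", "sample_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def sample_interval(self) -> float:
        """Position sampling interval f_s in seconds."""
        return 1.0 / self.sample_rate

    @property
    def center(self) -> tuple[float, float]:
        return (self.width / 2.0, self.height / 2.0)

    def contains(self, x, y) -> bool:
        import numpy as np

        return bool(
            np.all((x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.height))
        )
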