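"""Named frequency bands for parkinsonian LFP analysis.

The five bands follow the convention used for 6-OHDA rat corticostriatal
recordings: alpha (8-12 Hz), a split low-beta range (12-18 and 19-25 Hz),
the high-beta/low-gamma band (25-40 Hz) that carries the parkinsonian
oscillation, and high-gamma (40-50 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class BandTable:
    """Mapping of band name -> (f_lo, f_hi) in Hz.

    Invariants: f_lo < f_hi for every band; names unique (enforced by dict).
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "alpha": (8.0, 12.0),
            "low_beta_1": (12.0, 18.0),
            "low_beta_2": (19.0, 25.0),
            "high_beta": (25.0, 40.0),
            "high_gamma": (40.0, 50.0),
        }
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name!r}: f_lo={lo} must be < f_hi={hi}")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bands[name]

    def __iter__(self):
        return iter(self.bands)

    def items(self):
        return self.bands.items()


DEFAULT_BANDS = BandTable()
HIGH_BETA = DEFAULT_BANDS["high_beta"]
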