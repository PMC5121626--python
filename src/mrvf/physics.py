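"""Physical constants of the susceptibility-contrast experiment.

All susceptibilities are volume susceptibilities in ppm (SI convention);
``gamma`` is the proton gyromagnetic ratio in rad/s/T.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class Physics:
    """Constants shared by the simulator, the dictionaries and the analytic maps.

    Attributes
    ----------
    gamma:
        Proton gyromagnetic ratio, rad/s/T.
    b0:
        Static field strength, T.
    delta_chi_uspio_ppm:
        Susceptibility increase of blood after USPIO injection, ppm (SI).
        Specific to the contrast agent and to B0 (iron oxides saturate).
    delta_chi0_ppm:
        Susceptibility difference between fully deoxygenated and fully
        oxygenated hemoglobin, ppm (SI).
    hct:
        Systemic blood hematocrit; together with ``delta_chi0_ppm`` it maps
        oxygen saturation to the blood--tissue susceptibility difference
        dchi = delta_chi0 * hct * (1 - StO2).
    hct_micro:
        Microvascular hematocrit (systemic value scaled by the small-vessel
        factor 0.85), used by the quantitative-BOLD oxygenation fit.
    """

    gamma: float = 2.67502e8
    b0: float = 4.7
    delta_chi_uspio_ppm: float = 3.5
    delta_chi0_ppm: float = 3.32
    hct: float = 0.42
    hct_micro: float = 0.357

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Physics":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})

    @property
    def omega_per_ppm(self) -> float:
        """Angular frequency per ppm of susceptibility, rad/s (= gamma*B0*1e-6)."""
        return self.gamma * self.b0 * 1e-6


DEFAULT_PHYSICS = Physics()
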