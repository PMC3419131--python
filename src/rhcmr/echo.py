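"""Doppler echocardiographic estimation of pulmonary artery pressure.

The tricuspid regurgitant jet velocity (TRJV, m/s) gives the tricuspid
gradient by the modified Bernoulli equation TG = 4·v²; adding the estimated
right atrial pressure yields PA systolic pressure, and mean PA pressure is
estimated by the linear regression mPAP = 0.61·PASP + 2 mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class EchoMeasures:
    """Doppler inputs: jet velocity in m/s, RA pressure estimate in mmHg."""

    trjv: float
    rap_estimate: float

    def __post_init__(self) -> None:
        if self.trjv < 0:
            raise ValueError("trjv must be >= 0 m/s")
        if self.rap_estimate < 0:
            raise ValueError("rap_estimate must be >= 0 mmHg")


def tricuspid_gradient(trjv: float) -> float:
    """Modified Bernoulli gradient, mmHg: TG = 4·TRJV² (TRJV in m/s)."""
    if trjv < 0:
        raise ValueError("trjv must be >= 0 m/s")
    return 4.0 * trjv * trjv


def pa_systolic_pressure(trjv: float, rap: float) -> float:
    """PA systolic pressure, mmHg: tricuspid gradient + estimated RA pressure."""
    return tricuspid_gradient(trjv) + rap


def mpap_from_echo(pasp: float) -> float:
    """Mean PA pressure estimate, mmHg: 0.61·PASP + 2."""
    return 0.61 * pasp + 2.0


def echo_mpap(trjv: float, rap: float) -> float:
    """Composed convenience: TRJV (m/s) + RAP (mmHg) straight to mPAP (mmHg)."""
    return mpap_from_echo(pa_systolic_pressure(trjv, rap))
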