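"""Unit conventions and conversion constants.

Contours are supplied in millimetres, velocity maps in cm/s, pixel areas in
cm². Volumes are reported in mL, masses in g, pressures in mmHg. All
conversions route through the constants below so the convention lives in one
place.
"""

from decimal import ROUND_HALF_UP, Decimal

#: mm³ per mL (1 mL = 1 cm³ = 1000 mm³)
MM3_PER_ML = 1000.0

#: cm per mm
CM_PER_MM = 0.1

#: Density of myocardium, g/cm³; multiplies myocardial volume to give mass.
MYOCARDIAL_DENSITY_G_PER_CM3 = 1.05

#: mL per litre
ML_PER_L = 1000.0

#: Seconds per minute (beat-rate conversions)
S_PER_MIN = 60.0


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the given decimal place.

    Python's built-in ``round`` uses banker's rounding; clinical tables round
    half up (e.g. 95.45% -> 95%, 97.5% -> 98%).
    """
    q = Decimal(1).scaleb(-ndigits)
    r = float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
    return r if ndigits > 0 else float(int(r))
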