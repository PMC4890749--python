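"""Small unit helpers: concentration parsing and significant-figure rounding.

Internally everything is molar and minutes. Input readers accept the usual
suffixed concentration strings (``"20 uM"``, ``"5mM"``, ``"19 nM"``) and
convert once at the boundary.
"""

from __future__ import annotations

import math
import re

_SCALE = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "μM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}

_CONC_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*([mupµμn]?M)\s*$")


def parse_concentration(text: str | float) -> float:
    """Parse a concentration string into molar.

    Bare numbers (str or float) are taken as already molar.
    """
    if isinstance(text, (int, float)):
        return float(text)
    m = _CONC_RE.match(text)
    if m is None:
        try:
            return float(text)
        except ValueError:
            raise ValueError(f"cannot parse concentration {text!r}") from None
    value, unit = m.groups()
    return float(value) * _SCALE[unit]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def format_ratio(ratio: float, sig: int = 2) -> str:
    """Render a ligand:protein ratio like ``"6:1"`` or ``"1500:1"``.

    The ratio is rounded to ``sig`` significant figures, then shown against
    1 with an integer left-hand side (6.06 -> "6:1", 1515 -> "1500:1").
    """
    r = round_sig(ratio, sig)
    return f"{int(round(r))}:1"
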