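"""Number formatting shared by the report tables."""

from __future__ import annotations

import math


def format_p(p: float, floor: float = 1e-4) -> str:
    """Render a p-value in table style.

    Values below ``floor`` print as ``"< 0.0001"`` (effect tables) or
    ``"< 0.001"`` (baseline tables, ``floor=1e-3``); otherwise fixed
    decimals matching the floor's precision.
    """
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return "n.a."
    digits = max(0, -int(round(math.log10(floor))))
    if p < floor:
        return f"< {floor:.{digits}f}"
    return f"{p:.{digits}f}"


def format_or(or_: float, lo: float, hi: float) -> str:
    return f"{or_:.2f} ({lo:.2f}, {hi:.2f})"


def format_mean_sd(mean: float, sd: float) -> str:
    return f"{mean:.2f} ± {sd:.2f}"


def format_median_iqr(med: float, q1: float, q3: float) -> str:
    return f"{med:.2f} ({q1:.2f}-{q3:.2f})"


def format_count_pct(k: int, n: int) -> str:
    pct = 100.0 * k / n if n else float("nan")
    return f"{k} ({pct:.2f})"
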