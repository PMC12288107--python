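"""Published reference values from the larval-zebrafish cone phagocytosis study.

Two kinds of tables are bundled:

* ``VALIDATION_COUNTS`` — total OS-phagosome counts per cone subtype at two
  Zeitgeber times, quantified both manually and with the semi-automated
  detection tool.  These are the worked examples for
  :func:`phagoquant.evaluation.percent_difference`.
* ``LD_MEAN_DENSITY`` / ``DD_MEAN_DENSITY`` — mean phagosome densities
  (phagosomes per 10 μm of RPE) per cone subtype and Zeitgeber time under a
  normal 14h/10h light–dark cycle (LD) and under constant darkness (DD).
  They are the default means of the synthetic time-course generator.

Zeitgeber time (ZT) is hours after light onset; ZT0 = lights on,
ZT14 = lights off.
"""

from __future__ import annotations

SUBTYPES = ("UV", "blue", "green", "red")
CONDITIONS = ("LD", "DD")
ZT_POINTS = (1, 3, 5, 10, 16, 18, 23)

# (subtype, ZT) -> (manual count, automated count)
VALIDATION_COUNTS: dict[tuple[str, int], tuple[int, int]] = {
    ("UV", 16): (139, 146),
    ("UV", 1): (91, 83),
    ("blue", 16): (92, 98),
    ("blue", 1): (106, 99),
    ("green", 16): (224, 219),
    ("green", 1): (152, 136),
    ("red", 16): (34, 78),
    ("red", 1): (41, 65),
}

# subtype -> {ZT -> mean density per 10 um RPE}, normal light-dark cycle
LD_MEAN_DENSITY: dict[str, dict[int, float]] = {
    "UV": {1: 2.05, 3: 2.45, 5: 3.33, 10: 1.24, 16: 3.25, 18: 1.80, 23: 1.41},
    "blue": {1: 2.42, 3: 2.97, 5: 0.97, 10: 0.77, 16: 2.29, 18: 1.50, 23: 1.31},
    "green": {1: 2.93, 3: 3.33, 5: 2.45, 10: 4.18, 16: 5.10, 18: 3.38, 23: 4.09},
}

# subtype -> {ZT -> mean density per 10 um RPE}, constant darkness
DD_MEAN_DENSITY: dict[str, dict[int, float]] = {
    "UV": {1: 1.29, 3: 1.30, 5: 0.95, 10: 1.29, 16: 0.68, 18: 0.93, 23: 0.87},
    "blue": {1: 0.77, 3: 1.56, 5: 1.42, 10: 1.15, 16: 1.40, 18: 1.97, 23: 0.94},
    "green": {1: 4.10, 3: 2.86, 5: 1.59, 10: 2.42, 16: 1.56, 18: 3.67, 23: 1.47},
}


def mean_density_table(condition: str) -> dict[tuple[str, str, int], float]:
    """Flatten the per-condition density table to (subtype, condition, ZT) keys."""
    if condition == "LD":
        src = LD_MEAN_DENSITY
    elif condition == "DD":
        src = DD_MEAN_DENSITY
    else:
        raise ValueError(f"unknown light condition: {condition!r}")
    return {
        (subtype, condition, zt): dens
        for subtype, by_zt in src.items()
        for zt, dens in by_zt.items()
    }
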