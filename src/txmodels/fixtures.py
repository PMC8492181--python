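"""Built-in mechanistic parameter sets used across examples and tests.

All rates in s^-1, times in s.  The collection covers the regimes the
package is designed to probe:

* ``benchmark_1 .. benchmark_6`` — moment-validation sets spanning
  unimodal and bimodal number distributions, short and long elongation
  times, and both signs of the mature-mRNA Fano-factor deviation from 1.
  Note the quirk documented in ``docs/methods.md``: the nominal decay
  rate of sets 1, 3 and 5 is internally inconsistent with their reference
  mature-mRNA means (which correspond to d = 0.0016 s^-1), so mature-mRNA
  checks should use sets 2, 4 and 6.
* ``mapped_a / mapped_b / mapped_c`` — reducible sets (Delta > 0) whose
  two-state images are known to two significant figures; used to exercise
  the closed-form reduction map and distribution comparisons.
* ``peak_shift_b1 / b10 / b100`` — a family varying the Pol II
  binding/pause-entry rate b, showing the waiting-time density peak
  migrate toward zero as b grows.
* ``fano_dip`` — a set with randomness parameter just above 1 whose
  active Pol II Fano factor dips below 1 at intermediate elongation
  times.
* ``boundary_d / e / f`` — sets close to the R = 1 reducibility boundary
  where the two-state approximation of the active Pol II distribution is
  at its worst.
"""

from __future__ import annotations

from .models import MechanisticParams

__all__ = ["builtin_fixtures"]

_FIXTURES: dict[str, MechanisticParams] = {
    "benchmark_1": MechanisticParams(a=0.016, a_rev=0.08, b=0.16, b_rev=0.016, c=0.24, d=0.002, tau=273.62),
    "benchmark_2": MechanisticParams(a=0.112, a_rev=0.032, b=0.16, b_rev=0.016, c=0.24, d=0.016, tau=100.0),
    "benchmark_3": MechanisticParams(a=0.144, a_rev=0.032, b=0.96, b_rev=0.16, c=0.24, d=0.002, tau=273.62),
    "benchmark_4": MechanisticParams(a=0.144, a_rev=0.032, b=1.12, b_rev=0.8, c=0.24, d=0.1, tau=80.0),
    "benchmark_5": MechanisticParams(a=0.032, a_rev=0.032, b=0.16, b_rev=0.016, c=0.32, d=0.002, tau=273.62),
    "benchmark_6": MechanisticParams(a=0.016, a_rev=0.032, b=0.16, b_rev=0.016, c=0.4, d=0.005, tau=50.0),
    "mapped_a": MechanisticParams(a=0.001, a_rev=0.001, b=0.16, b_rev=0.016, c=0.24, d=0.0016, tau=273.62),
    "mapped_b": MechanisticParams(a=0.144, a_rev=0.032, b=0.016, b_rev=0.56, c=0.24, d=0.0016, tau=273.62),
    "mapped_c": MechanisticParams(a=0.032, a_rev=0.032, b=0.16, b_rev=0.016, c=0.32, d=0.0016, tau=273.62),
    "peak_shift_b1": MechanisticParams(a=0.1, a_rev=0.1, b=1.0, b_rev=4.0, c=10.0, d=0.0016, tau=273.62),
    "peak_shift_b10": MechanisticParams(a=0.1, a_rev=0.1, b=10.0, b_rev=4.0, c=10.0, d=0.0016, tau=273.62),
    "peak_shift_b100": MechanisticParams(a=0.1, a_rev=0.1, b=100.0, b_rev=4.0, c=10.0, d=0.0016, tau=273.62),
    "fano_dip": MechanisticParams(a=0.09, a_rev=0.032, b=0.16, b_rev=0.0125, c=0.4, d=0.0016, tau=273.62),
    "boundary_d": MechanisticParams(a=0.0336, a_rev=0.006, b=0.16, b_rev=0.016, c=0.24, d=0.0016, tau=13.65),
    "boundary_e": MechanisticParams(a=0.072, a_rev=0.0288, b=0.16, b_rev=0.016, c=0.24, d=0.0016, tau=8.76),
    "boundary_f": MechanisticParams(a=0.08, a_rev=0.005, b=2.0, b_rev=0.0001, c=1.36, d=0.0016, tau=3.0),
}


def builtin_fixtures() -> dict[str, MechanisticParams]:
    """A fresh copy of the named built-in parameter sets."""
    return dict(_FIXTURES)
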