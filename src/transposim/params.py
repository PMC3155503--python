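"""Kinetic parameters of the transposon-control models.

All rates are per hour; molecule counts are absolute copy numbers
(``#mol``), not concentrations.  A single :class:`ParameterSet` houses
every rate constant used by any of the three model variants; constants
that belong to a reaction absent from a variant are simply inert there.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Iterator, Mapping


@dataclass(frozen=True)
class ParameterSet:
    """The 25 rate constants and fractions of the transposon-RNAi models.

    Attributes
    ----------
    j : float
        Rate of VLP integration attempts into the genome (hr^-1).
    f : float
        Fraction of integration attempts that succeed (dimensionless,
        in [0, 1]).
    v_ta : float
        Transcription rate of active transposons (hr^-1).
    v_ts : float
        Transcription rate of silenced transposons (hr^-1); produces the
        short / antisense transcript.
    t_m : float
        Nuclear export of mRNA (hr^-1).
    t_an : float
        Nuclear export of antisense RNA (hr^-1); antisense variant only.
    q : float
        VLP production (#mol^-1 hr^-1); second order in cytoplasmic mRNA.
    d_v : float
        VLP decay (hr^-1).
    u : float
        Reactivation of a silenced transposon (hr^-1).
    h_b : float
        Basal heterochromatin formation (hr^-1).
    h_s : float
        siRNA-guided (RITS) heterochromatin formation (#mol^-1 hr^-1).
    p_n : float
        Unprimed RdRP dsRNA synthesis from nuclear RNA (hr^-1).
    p_nx : float
        Nuclear sense-antisense dsRNA formation (#mol^-1 hr^-1).
    d_r : float
        Decay of nuclear (antisense/short) RNA (hr^-1).
    p_c : float
        Unprimed RdRP dsRNA synthesis from cytoplasmic mRNA (hr^-1).
    p_cx : float
        Cytoplasmic sense-antisense dsRNA formation (#mol^-1 hr^-1).
    p_cxx : float
        dsRNA formation by hairpin folding of cytoplasmic mRNA (hr^-1).
    g : float
        siRNA-primed RdRP amplification (#mol^-1 hr^-1).
    b : float
        RISC slicing activity (#mol^-1 hr^-1).
    d_m : float
        Decay of nuclear and cytoplasmic mRNA (hr^-1).
    g_s : float
        Dicer cleavage of dsRNA (hr^-1).
    n : float
        Number of siRNAs produced per diced dsRNA (count, >= 1).
    d_s : float
        siRNA decay (hr^-1).
    v_s : float
        Saturating RNase degradation of mRNA (#mol^-1 hr^-1).
    k_s : float
        Saturation constant of the RNase term (#mol).
    """

    j: float = 0.1
    f: float = 0.1
    v_ta: float = 16.0
    v_ts: float = 1.6
    t_m: float = 0.45
    t_an: float = 0.45
    q: float = 1e-5
    d_v: float = 2.0
    u: float = 0.02
    h_b: float = 0.01
    h_s: float = 0.001
    p_n: float = 0.002
    p_nx: float = 2e-4
    d_r: float = 0.28
    p_c: float = 0.002
    p_cx: float = 2.5e-4
    p_cxx: float = 0.002
    g: float = 0.002
    b: float = 0.008
    d_m: float = 0.14
    g_s: float = 2.0
    n: float = 10.0
    d_s: float = 2.8
    v_s: float = 800.0
    k_s: float = 5.0

    def __post_init__(self) -> None:
        for name, value in self.items():
            if value < 0:
                raise ValueError(f"parameter {name!r} must be >= 0, got {value}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must lie in [0, 1], got {self.f}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")

    # -- mapping-style helpers -------------------------------------------
    @classmethod
    def names(cls) -> tuple[str, ...]:
        return tuple(fld.name for fld in fields(cls))

    def items(self) -> Iterator[tuple[str, float]]:
        for name in self.names():
            yield name, getattr(self, name)

    def as_dict(self) -> dict[str, float]:
        return dict(self.items())

    def __getitem__(self, name: str) -> float:
        if name not in self.names():
            raise KeyError(name)
        return getattr(self, name)

    def with_updates(self, **updates: float) -> "ParameterSet":
        """Return a copy with the given parameters replaced.

        Unknown parameter names raise ``KeyError`` carrying the name, so
        callers (e.g. the command line) can report typos precisely.
        """
        unknown = set(updates) - set(self.names())
        if unknown:
            raise KeyError(
                f"unknown parameter(s): {', '.join(sorted(unknown))}; "
                f"valid names are {', '.join(self.names())}"
            )
        return replace(self, **updates)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ParameterSet":
        return cls().with_updates(**dict(mapping))


_DEFAULTS = ParameterSet()


def default_parameters() -> ParameterSet:
    """Return the reference parameter set (the published defaults).

    The returned object is immutable; use :meth:`ParameterSet.with_updates`
    to derive modified sets.
    """
    return _DEFAULTS
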