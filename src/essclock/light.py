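"""Square-wave light forcing and light-dark experiment protocols.

The light input is a dimensionless square wave L(t) in {floor, 1} with ``t = 0``
taken as dawn.  A protocol entrains the system with repeated photoperiodic
cycles and then releases it into a constant regime: constant light (LL) or
constant dark (DD).  Releasing with ``photoperiod P = 24`` or ``P = 0`` from
the start gives LL and DD directly.

The floor is 0 by default; original (non-extended) S-System models place
light inside a power law, where a base of exactly zero with a negative
exponent is undefined, so those models use a floor of 0.001 instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field


_VALID_REGIMES = ("LL", "DD", "none")
_VALID_FLOORS = (0.0, 0.001)


@dataclass(frozen=True)
class LightProtocol:
    """Entrainment-then-release light schedule.

    Parameters
    ----------
    photoperiod : float
        Hours of light per 24 h cycle, in [0, 24].
    entrainment_cycles : int
        Number of full cycles run before recording; informational for
        simulation helpers (the signal itself is defined for all t >= 0).
    release_regime : {"LL", "DD", "none"}
        Constant regime entered at ``release_time``; "none" cycles forever.
    release_time : float or None
        Hours from dawn at which the constant regime begins.  Defaults to the
        dawn ending the entrainment cycles (24 * entrainment_cycles).
    light_floor : float
        Value of the signal in darkness, 0.0 or 0.001.
    """

    photoperiod: float = 12.0
    entrainment_cycles: int = 10
    release_regime: str = "none"
    release_time: float | None = None
    light_floor: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.photoperiod <= 24.0:
            raise ValueError(f"photoperiod must be in [0, 24], got {self.photoperiod}")
        if self.entrainment_cycles < 0:
            raise ValueError("entrainment_cycles must be >= 0")
        if self.release_regime not in _VALID_REGIMES:
            raise ValueError(f"release_regime must be one of {_VALID_REGIMES}")
        if self.light_floor not in _VALID_FLOORS:
            raise ValueError(f"light_floor must be one of {_VALID_FLOORS}")
        if self.release_time is None and self.release_regime != "none":
            object.__setattr__(self, "release_time", 24.0 * self.entrainment_cycles)

    @property
    def released(self) -> bool:
        return self.release_regime != "none"


def light_signal(t: float, protocol: LightProtocol) -> float:
    """Evaluate the square-wave light input at time ``t`` (hours, t >= 0).

    Before release the signal is 1 on [dawn, dusk) of every cycle
    (``0 <= t mod 24 < P``) and the floor otherwise; after release it is
    constant 1 (LL) or constant floor (DD).
    """
    if protocol.released and t >= protocol.release_time:
        return 1.0 if protocol.release_regime == "LL" else protocol.light_floor
    if (t % 24.0) < protocol.photoperiod:
        return 1.0
    return protocol.light_floor


def switch_times(protocol: LightProtocol, t_start: float, t_end: float) -> list[float]:
    """Discontinuity times of the light signal in the half-open window (t_start, t_end].

    Returns every dawn/dusk transition before release, plus the release
    instant itself when the regime changes there; nothing after release into
    a constant regime.  Used to restart the integrator at each jump.
    """
    if t_start >= t_end:
        raise ValueError("t_start must be < t_end")
    P = protocol.photoperiod
    cutoff = protocol.release_time if protocol.released else t_end
    times: list[float] = []
    if 0.0 < P < 24.0:
        cycle = int(t_start // 24.0)
        while True:
            dusk = cycle * 24.0 + P
            dawn = (cycle + 1) * 24.0
            advanced = False
            for tc in (dusk, dawn):
                if tc > cutoff:
                    break
                if t_start < tc <= t_end:
                    times.append(tc)
                    advanced = True
            if dawn > min(cutoff, t_end):
                break
            cycle += 1
            if not advanced and dusk > t_end:
                break
    if protocol.released and t_start < protocol.release_time <= t_end:
        before = light_signal(protocol.release_time - 1e-9, protocol)
        after = light_signal(protocol.release_time, protocol)
        if before != after and protocol.release_time not in times:
            times.append(protocol.release_time)
    return sorted(set(times))
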