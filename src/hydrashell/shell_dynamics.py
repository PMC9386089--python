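"""Water-exchange dynamics of the first hydration shell.

Implements the "direct" mean-residence-time estimator

    MRT(t*) = t_samp · CN_av / N_ex(t*)

where t_samp is the analyzed span (ps), CN_av the mean coordination number
over that span and N_ex(t*) the number of boundary crossings that qualify as
genuine exchange events at persistence threshold t*: a crossing counts iff
both the state left behind and the newly entered state persist strictly
longer than t*.  Entries and exits both count.  At t* = 0 every crossing
counts and N_ex equals the total number of membership transitions.

Also provides the coordination-number lifetime spectrum: the CN time series
is segmented into maximal constant-CN episodes, optionally bridging
excursions away from a value that last no longer than t*.

Durations follow one uniform convention: a state run of m frames lasts m·dt.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .shell_structure import ShellMetrics, ShellOccupancySeries

__all__ = [
    "ExchangeEvent",
    "ExchangeEventLog",
    "MRTResult",
    "CNLifetimeSpectrum",
    "detect_exchanges",
    "mrt_direct",
    "mrt_from_counts",
    "cn_lifetimes",
    "compare_ions",
    "round_half_up",
]

FS_PER_PS = 1000.0


def round_half_up(x: float) -> int:
    """Presentation rounding with .5 always rounding up (no banker's ties)."""
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class ExchangeEvent:
    molecule: int
    time: float  # fs, time of the first frame in the new state
    direction: str  # "entry" | "exit"
    persistence: float  # fs, duration of the new state


@dataclass(frozen=True)
class ExchangeEventLog:
    events: tuple[ExchangeEvent, ...]
    t_star: float  # ps

    @property
    def n_ex(self) -> int:
        return len(self.events)

    def to_json(self) -> str:
        return json.dumps(
            {
                "t_star_ps": self.t_star,
                "n_ex": self.n_ex,
                "events": [
                    {
                        "molecule": e.molecule,
                        "time_fs": e.time,
                        "direction": e.direction,
                        "persistence_fs": e.persistence,
                    }
                    for e in self.events
                ],
            },
            indent=2,
            sort_keys=True,
        )


@dataclass(frozen=True)
class MRTResult:
    t_star: float  # ps
    t_samp: float  # ps
    cn_av: float
    n_ex: int
    mrt: float | None  # ps; None when n_ex == 0 (undefined, not infinite)

    @property
    def mrt_rounded(self) -> int | None:
        return None if self.mrt is None else round_half_up(self.mrt)


@dataclass(frozen=True)
class CNLifetimeSpectrum:
    """Per-CN episode statistics: mean/longest lifetime (ps) and count."""

    t_star: float  # ps
    lifetimes: dict[int, tuple[float, float, int]]  # cn -> (mean, longest, episodes)

    def longest(self, cn: int) -> float:
        return self.lifetimes[cn][1]

    @property
    def cn_with_longest_lifetime(self) -> int:
        return max(self.lifetimes, key=lambda c: self.lifetimes[c][1])

    def to_tsv(self) -> str:
        lines = [f"# t_star_ps\t{self.t_star:.6g}", "CN\tmean_ps\tlongest_ps\tepisodes"]
        for cn in sorted(self.lifetimes):
            mean, longest, n = self.lifetimes[cn]
            lines.append(f"{cn}\t{mean:.6g}\t{longest:.6g}\t{n}")
        return "\n".join(lines) + "\n"


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode a 1-D state vector → list of (value, start, length)."""
    if states.size == 0:
        return []
    change = np.nonzero(np.diff(states) != 0)[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [states.size]])
    return [(int(states[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def detect_exchanges(series: ShellOccupancySeries, t_star: float) -> ExchangeEventLog:
    """Count genuine exchange events at persistence threshold ``t_star`` (ps).

    Each molecule's inside/outside membership string is run-length scanned.
    A boundary crossing (start of a run) is a genuine exchange iff the
    durations of both the preceding run and the new run strictly exceed t*,
    runs truncated by the trajectory ends included at their observed length.
    At t* = 0 every crossing therefore counts.  Entries and exits both count
    toward N_ex.
    """
    if t_star < 0:
        raise ValueError("t_star must be non-negative")
    dt = series.dt
    span_ps = series.span / FS_PER_PS
    if t_star >= span_ps:
        raise ValueError(
            f"t_star={t_star:g} ps is not below the trajectory span {span_ps:g} ps"
        )
    t_star_fs = t_star * FS_PER_PS
    events: list[ExchangeEvent] = []
    for mol in range(series.n_molecules):
        runs = _runs(series.member_mask[:, mol].astype(np.int8))
        for j in range(1, len(runs)):
            prev_dur = runs[j - 1][2] * dt
            new_dur = runs[j][2] * dt
            if prev_dur > t_star_fs and new_dur > t_star_fs:
                direction = "entry" if runs[j][0] == 1 else "exit"
                events.append(
                    ExchangeEvent(
                        molecule=mol,
                        time=float(series.times[runs[j][1]]),
                        direction=direction,
                        persistence=float(new_dur),
                    )
                )
    events.sort(key=lambda e: (e.time, e.molecule))
    return ExchangeEventLog(tuple(events), float(t_star))


def mrt_from_counts(t_samp: float, cn_av: float, n_ex: int, t_star: float = 0.0) -> MRTResult:
    """Direct-method MRT from already-known counts (t_samp in ps)."""
    mrt = None if n_ex == 0 else t_samp * cn_av / n_ex
    return MRTResult(float(t_star), float(t_samp), float(cn_av), int(n_ex), mrt)


def mrt_direct(
    series: ShellOccupancySeries, t_star: float, t_samp: float | None = None
) -> MRTResult:
    """Direct-method mean residence time at threshold ``t_star`` (ps).

    ``t_samp`` defaults to the series' own sampled span (n_frames · dt, in
    ps); CN_av is the mean coordination number over the same span.  With
    N_ex = 0 the MRT is reported as undefined (None), never as infinity.
    """
    if t_samp is None:
        t_samp = series.span / FS_PER_PS
    log = detect_exchanges(series, t_star)
    return mrt_from_counts(t_samp, series.cn_mean, log.n_ex, t_star)


def _bridge(mask: np.ndarray, max_gap_frames: int) -> np.ndarray:
    """Fill interior False-runs of length ≤ max_gap_frames flanked by True."""
    if max_gap_frames <= 0:
        return mask
    out = mask.copy()
    for value, start, length in _runs(mask.astype(np.int8)):
        if value == 0 and length <= max_gap_frames and start > 0 and start + length < mask.size:
            out[start : start + length] = True
    return out


def cn_lifetimes(
    series: ShellOccupancySeries, t_star: float, bridged: bool = True
) -> CNLifetimeSpectrum:
    """Lifetime spectrum of coordination-number values.

    For each observed CN value the time series is viewed as "at this CN /
    away from it"; with ``bridged=True`` (default) excursions away lasting at
    most t* are bridged before segmentation, so brief interruptions do not
    split an episode.  Episode duration is (frames in episode) · dt.  The
    unbridged variant (``bridged=False``) segments the raw series.
    """
    if t_star < 0:
        raise ValueError("t_star must be non-negative")
    dt = series.dt
    cn = series.cn_per_frame
    max_gap = int(np.floor(t_star * FS_PER_PS / dt + 1e-9)) if bridged else 0
    lifetimes: dict[int, tuple[float, float, int]] = {}
    for value in np.unique(cn):
        mask = _bridge(cn == value, max_gap)
        durations = [
            length * dt / FS_PER_PS
            for v, _start, length in _runs(mask.astype(np.int8))
            if v == 1
        ]
        lifetimes[int(value)] = (
            float(np.mean(durations)),
            float(np.max(durations)),
            len(durations),
        )
    return CNLifetimeSpectrum(float(t_star), lifetimes)


# ---------------------------------------------------------------------------
# comparison report
# ---------------------------------------------------------------------------

def _flag(a: float | None, b: float | None) -> str:
    if a is None or b is None:
        return "undefined"
    if np.isclose(a, b, rtol=0.0, atol=1e-12):
        return "equal"
    return "greater" if a > b else "less"


def compare_ions(
    metrics_a: ShellMetrics,
    metrics_b: ShellMetrics,
    dynamics_a: dict[float, MRTResult] | None = None,
    dynamics_b: dict[float, MRTResult] | None = None,
    lifetimes_a: dict[float, CNLifetimeSpectrum] | None = None,
    lifetimes_b: dict[float, CNLifetimeSpectrum] | None = None,
    label_a: str = "A",
    label_b: str = "B",
) -> list[dict[str, object]]:
    """Side-by-side structural/dynamical comparison of two ions.

    Returns ordered rows of ``{property, <label_a>, <label_b>, flag}`` where
    ``flag`` states whether the first ion's value is greater than, less than
    or equal to the second's (``undefined`` when a value is missing).
    Formatting to the printed precision is left to the reporting layer.
    """
    rows: list[dict[str, object]] = []

    def add(name: str, va: float | None, vb: float | None) -> None:
        rows.append({"property": name, label_a: va, label_b: vb, "flag": _flag(va, vb)})

    add("r_bar_angstrom", metrics_a.r_bar, metrics_b.r_bar)
    add("cn_mean", metrics_a.cn_mean, metrics_b.cn_mean)
    add("tilt_mean_deg", metrics_a.tilt_mean_deg, metrics_b.tilt_mean_deg)
    add("sigma2_angstrom2", metrics_a.sigma2, metrics_b.sigma2)
    add("eccentricity_angstrom", metrics_a.eccentricity, metrics_b.eccentricity)
    for t_star in sorted((dynamics_a or {}).keys() | (dynamics_b or {}).keys()):
        ra = (dynamics_a or {}).get(t_star)
        rb = (dynamics_b or {}).get(t_star)
        add(f"n_ex_tstar_{t_star:g}ps", ra.n_ex if ra else None, rb.n_ex if rb else None)
        add(f"mrt_ps_tstar_{t_star:g}ps", ra.mrt if ra else None, rb.mrt if rb else None)
    for t_star in sorted((lifetimes_a or {}).keys() | (lifetimes_b or {}).keys()):
        la = (lifetimes_a or {}).get(t_star)
        lb = (lifetimes_b or {}).get(t_star)
        va = max(v[1] for v in la.lifetimes.values()) if la else None
        vb = max(v[1] for v in lb.lifetimes.values()) if lb else None
        add(f"longest_cn_lifetime_ps_tstar_{t_star:g}ps", va, vb)
    return rows
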