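"""Mode-shift scenarios: stepwise share transfers and relative fatality risk.

A scenario moves commute distance share in fixed percentage-point steps
from one mode to another (e.g. 2W riders buying cars, or pedestrians
buying 2W), holding total distance constant. Expected fatalities follow
the multiplicative form

    f = walk^e_walk · cycle^e_cycle · IPT^e_IPT · bus^e_bus · 2W^e_2W · car^e_car

with the exponents taken from the fitted regression (final-model
posterior means). The relative risk (RR) of a shifted share vector is its
f divided by the baseline's f, so the baseline RR is one and any common
scale factor between shares and absolute distances cancels.

Because log RR of a two-mode shift is concave in the shifted fraction,
a 2W→car curve either rises monotonically (car-poor baselines), declines
monotonically (car-rich baselines past the critical point), or rises to
an interior peak — the critical mix beyond which further shift to cars
improves safety.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

#: scenario-model exponents as printed (rounded final-model means)
EQ_EXPONENTS: dict[str, float] = {
    "walk": -0.36,
    "cycle": -0.2,
    "IPT": -0.23,
    "bus": 0.07,
    "2W": 0.39,
    "car": 0.26,
}
#: full-precision final-model posterior means
FULL_PRECISION_EXPONENTS: dict[str, float] = {
    "walk": -0.355,
    "cycle": -0.200,
    "IPT": -0.234,
    "bus": 0.066,
    "2W": 0.390,
    "car": 0.263,
}
SCENARIO_MODES = ("walk", "cycle", "IPT", "bus", "2W", "car")

#: the three studied shift directions
STANDARD_SCENARIOS = {
    "A": ("2W", "car"),
    "B": ("walk", "2W"),
    "C": ("cycle", "2W"),
}


@dataclass(frozen=True)
class ScenarioDef:
    """One shift direction with step size, horizon and risk exponents."""

    from_mode: str
    to_mode: str
    step_pp: float = 0.5  # percentage points moved per step
    n_steps: int = 10  # curve length including the baseline
    exponents: Mapping[str, float] = field(
        default_factory=lambda: dict(EQ_EXPONENTS)
    )

    def __post_init__(self) -> None:
        if self.from_mode == self.to_mode:
            raise ValueError("from_mode and to_mode must differ")
        if self.step_pp <= 0:
            raise ValueError("step_pp must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        missing = [m for m in SCENARIO_MODES if m not in self.exponents]
        if missing:
            raise ValueError(f"exponents missing for modes {missing}")


class ShareTruncation(Exception):
    """Signals that a step would drive the source-mode share negative."""


@dataclass(frozen=True)
class RRCurve:
    """Relative-risk trajectory over shift steps; step 0 is the baseline."""

    baseline_shares: Mapping[str, float]
    steps: tuple[tuple[Mapping[str, float], float], ...]  # (shares, RR)
    truncated: bool

    @property
    def rr(self) -> tuple[float, ...]:
        return tuple(r for _, r in self.steps)

    def __len__(self) -> int:
        return len(self.steps)


def shift_shares(
    shares: Mapping[str, float], definition: ScenarioDef, step_index: int
) -> dict[str, float]:
    """Shares after ``step_index`` steps of the shift; totals are conserved.

    Raises :class:`ShareTruncation` when the source-mode share would go
    negative (the scenario horizon ends at the last valid step).
    """
    if step_index < 0:
        raise ValueError("step_index must be >= 0")
    moved = step_index * definition.step_pp / 100.0
    out = {m: float(v) for m, v in shares.items()}
    new_from = out[definition.from_mode] - moved
    if new_from < 0:
        raise ShareTruncation(
            f"{definition.from_mode} share would be {new_from:.4f} "
            f"at step {step_index}"
        )
    out[definition.from_mode] = new_from
    out[definition.to_mode] = out[definition.to_mode] + moved
    return out


def relative_risk(
    shares: Mapping[str, float],
    baseline: Mapping[str, float],
    exponents: Mapping[str, float] | None = None,
) -> float:
    """RR = Π_m (share_m / baseline_m)^{e_m}.

    Scale factors common to both vectors cancel, so shares and absolute
    distances give identical RR. A zero share on a mode with a non-zero
    exponent has no finite risk ratio and is rejected.
    """
    exponents = EQ_EXPONENTS if exponents is None else exponents
    log_rr = 0.0
    for mode, e in exponents.items():
        if e == 0:
            continue
        s = float(shares.get(mode, 0.0))
        b = float(baseline.get(mode, 0.0))
        if s <= 0 or b <= 0:
            raise ValueError(
                f"mode {mode!r} has non-positive share with exponent {e}"
            )
        log_rr += e * (math.log(s) - math.log(b))
    return math.exp(log_rr)


def run_scenario(baseline: Mapping[str, float], definition: ScenarioDef) -> RRCurve:
    """Evaluate RR over steps 0..n_steps-1, truncating at invalid shares.

    A step is invalid if the source share would go negative, or would hit
    exactly zero while its exponent is non-zero (RR undefined there).
    """
    steps = []
    truncated = False
    e_from = definition.exponents.get(definition.from_mode, 0.0)
    for i in range(definition.n_steps):
        try:
            shifted = shift_shares(baseline, definition, i)
        except ShareTruncation:
            truncated = True
            break
        if shifted[definition.from_mode] == 0 and e_from != 0:
            truncated = True
            break
        rr = 1.0 if i == 0 else relative_risk(shifted, baseline, definition.exponents)
        steps.append((shifted, rr))
    return RRCurve(
        baseline_shares=dict(baseline), steps=tuple(steps), truncated=truncated
    )


def detect_turning_point(curve: RRCurve | Sequence[float], kind: str = "min"):
    """Index of the first strictly interior local extremum of the RR curve.

    ``kind='min'`` finds a local minimum, ``kind='max'`` the peak marking the
    critical mode mix of a 2W→car shift. Returns ``None`` for monotone
    curves.
    """
    rr = list(curve.rr) if isinstance(curve, RRCurve) else list(curve)
    if len(rr) < 3:
        raise ValueError("curve must have at least 3 points")
    sign = 1.0 if kind == "min" else -1.0
    if kind not in ("min", "max"):
        raise ValueError("kind must be 'min' or 'max'")
    for i in range(1, len(rr) - 1):
        if sign * rr[i] < sign * rr[i - 1] and sign * rr[i] < sign * rr[i + 1]:
            return i
    return None


def run_standard_scenarios(
    baselines: Mapping[str, Mapping[str, float]],
    exponents: Mapping[str, float] | None = None,
    step_pp: float = 0.5,
    n_steps: int = 10,
) -> pd.DataFrame:
    """All three shift directions for every baseline (e.g. cluster profile).

    Returns a long table: baseline, scenario, step, per-mode shares, RR and
    the truncation flag.
    """
    exponents = dict(EQ_EXPONENTS if exponents is None else exponents)
    rows = []
    for name, baseline in baselines.items():
        for scen, (from_mode, to_mode) in STANDARD_SCENARIOS.items():
            definition = ScenarioDef(
                from_mode, to_mode, step_pp=step_pp, n_steps=n_steps,
                exponents=exponents,
            )
            curve = run_scenario(baseline, definition)
            for step, (shares, rr) in enumerate(curve.steps):
                row = {"baseline": name, "scenario": scen, "step": step, "rr": rr,
                       "truncated": curve.truncated}
                for m in SCENARIO_MODES:
                    row[f"share_{m}"] = shares.get(m, 0.0)
                rows.append(row)
    return pd.DataFrame(rows)


def plot_rr_curves(df: pd.DataFrame, path) -> None:
    """Write a relative-risk-vs-step panel per scenario from the long table
    produced by :func:`run_standard_scenarios`."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scen_names = sorted(df["scenario"].unique())
    fig, axes = plt.subplots(1, len(scen_names), figsize=(4 * len(scen_names), 3.2),
                             sharey=True)
    axes = [axes] if len(scen_names) == 1 else list(axes)
    for ax, scen in zip(axes, scen_names):
        sub = df[df["scenario"] == scen]
        for name, grp in sub.groupby("baseline"):
            ax.plot(grp["step"], grp["rr"], marker="o", ms=3, label=name)
        from_mode, to_mode = STANDARD_SCENARIOS.get(scen, ("?", "?"))
        ax.set_title(f"{scen}: {from_mode} → {to_mode}")
        ax.set_xlabel("shift step (0.5 pp each)")
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    axes[0].set_ylabel("relative risk")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


__all__ = [
    "EQ_EXPONENTS",
    "FULL_PRECISION_EXPONENTS",
    "SCENARIO_MODES",
    "STANDARD_SCENARIOS",
    "ScenarioDef",
    "ShareTruncation",
    "RRCurve",
    "shift_shares",
    "relative_risk",
    "run_scenario",
    "detect_turning_point",
    "run_standard_scenarios",
    "plot_rr_curves",
]
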