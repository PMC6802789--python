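"""Generative model for colour-wheel cueing sessions.

Colour responses follow the Zhang–Luck two-component mixture: with
probability rho (probability of encoding) the signed response error is
von Mises(0, kappa); otherwise the response is a blind guess, uniform on the
wheel. Detection RTs are lognormal with additive condition effects on the
log scale. Contamination (misses, false alarms on catch trials, pre-target
responses) is injected at configurable per-trial rates.

Default generating values place each condition at the posterior medians
reported for the two experiments: E1 neutral cell at rho = 0.992,
kappa = 9.08, RT = 359.86 ms, with the valid-invalid contrasts -21.70 ms /
+0.008 / +0.45 split symmetrically around it; E2 analogues per SOA,
including the +1.26 kappa benefit of neutral over spatial cues at the
100 ms SOA. Within-subject RT spread and subject-level spreads are not
reported quantities and carry realistic defaults (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import design as _design
from ._angles import rad2deg, wrap_deg

__all__ = [
    "GenerativeParams",
    "SimulatedDataset",
    "condition_cell",
    "default_params",
    "sample_colour_response",
    "sample_rt",
    "simulate_subject",
    "simulate_experiment",
]


def condition_cell(cue_type, soa_ms, experiment: str):
    """Condition-cell label: cue_type for E1, 'cue@soa' for E2."""
    if experiment == "E1":
        return np.asarray(cue_type, dtype=object) if not np.isscalar(cue_type) else cue_type
    cue = np.asarray(cue_type, dtype=object)
    soa = np.asarray(soa_ms)
    if cue.ndim == 0:
        return f"{cue_type}@{int(soa_ms)}"
    return np.array([f"{c}@{int(s)}" for c, s in zip(cue, soa)], dtype=object)


@dataclass
class GenerativeParams:
    """True population-level parameters for one experiment.

    Condition keys are cells as produced by :func:`condition_cell`.
    ``rt_effects`` are additive log-ms offsets relative to ``rt_log_mean``.
    ``subject_sds`` hold the SDs of subject-level intercept deviations on
    the log-ms, logit-rho and log-kappa scales respectively.
    """

    experiment: str
    rt_log_mean: float
    rt_effects: dict = field(default_factory=dict)
    rt_log_sd_within: float = 0.18
    subject_sds: dict = field(
        default_factory=lambda: {"rt": 0.15, "rho_logit": 0.5, "log_kappa": 0.2}
    )
    rho_by_condition: dict = field(default_factory=dict)
    kappa_by_condition: dict = field(default_factory=dict)
    miss_rate: float = 0.0032
    false_alarm_rate: float = 0.0302
    pre_target_rate: float = 0.0122
    timeout_ms: float = 1500.0

    def __post_init__(self):
        for name in ("miss_rate", "false_alarm_rate", "pre_target_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for c, rho in self.rho_by_condition.items():
            if not 0.0 <= rho <= 1.0:
                raise ValueError(f"rho for cell {c!r} must be in [0, 1], got {rho}")
        for c, kappa in self.kappa_by_condition.items():
            if kappa <= 0:
                raise ValueError(f"kappa for cell {c!r} must be > 0, got {kappa}")

    @property
    def cells(self) -> list:
        return list(self.rho_by_condition)

    def rt_median_ms(self, cell) -> float:
        return float(np.exp(self.rt_log_mean + self.rt_effects[cell]))

    def true_effects(self) -> dict:
        """Generating cueing contrasts on the reported scales.

        Keys match the labels of :func:`cuewheel.inference.effect_table`:
        ``"rt_ms valid - invalid"``, ``"rho valid - invalid"``, ``"kappa
        valid - invalid"`` (with an ``@soa`` suffix for E2 cells) and
        ``"kappa neutral - spatial"`` where a neutral cell exists.
        """
        suffixes = sorted({("@" + c.split("@")[1]) if "@" in c else "" for c in self.cells})
        out = {}
        for sfx in suffixes:
            v, i, n = (f"valid{sfx}", f"invalid{sfx}", f"neutral{sfx}")
            out[f"rt_ms valid - invalid{sfx}"] = self.rt_median_ms(v) - self.rt_median_ms(i)
            out[f"rho valid - invalid{sfx}"] = (
                self.rho_by_condition[v] - self.rho_by_condition[i]
            )
            out[f"kappa valid - invalid{sfx}"] = (
                self.kappa_by_condition[v] - self.kappa_by_condition[i]
            )
            if n in self.kappa_by_condition:
                pooled = float(
                    np.exp(
                        0.5
                        * (
                            np.log(self.kappa_by_condition[v])
                            + np.log(self.kappa_by_condition[i])
                        )
                    )
                )
                out[f"kappa neutral - spatial{sfx}"] = self.kappa_by_condition[n] - pooled
        return out

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GenerativeParams":
        return cls(**json.loads(text))


def _params_from_cell_table(experiment, rt_ms, rho, kappa, **kw) -> GenerativeParams:
    ref = "neutral" if experiment == "E1" else "neutral@800"
    log_ref = float(np.log(rt_ms[ref]))
    effects = {c: float(np.log(v)) - log_ref for c, v in rt_ms.items()}
    return GenerativeParams(
        experiment=experiment,
        rt_log_mean=log_ref,
        rt_effects=effects,
        rho_by_condition=dict(rho),
        kappa_by_condition=dict(kappa),
        **kw,
    )


def default_params(experiment: str) -> GenerativeParams:
    """Default generating parameters for E1 or E2, anchored to the reported
    posterior medians of the two experiments (see module docstring)."""
    if experiment == "E1":
        return _params_from_cell_table(
            "E1",
            rt_ms={"neutral": 359.86, "valid": 349.01, "invalid": 370.71},
            rho={"neutral": 0.992, "valid": 0.996, "invalid": 0.988},
            kappa={"neutral": 9.08, "valid": 9.305, "invalid": 8.855},
            miss_rate=0.0032,
            false_alarm_rate=0.0302,
            pre_target_rate=0.0122,
        )
    if experiment == "E2":
        return _params_from_cell_table(
            "E2",
            rt_ms={
                "neutral@100": 404.02, "valid@100": 407.33, "invalid@100": 400.71,
                "neutral@800": 393.78, "valid@800": 411.25, "invalid@800": 376.31,
            },
            rho={
                "neutral@100": 0.995, "valid@100": 0.9965, "invalid@100": 0.9935,
                "neutral@800": 0.995, "valid@800": 0.993, "invalid@800": 0.997,
            },
            kappa={
                # neutral carries a +1.26 fidelity benefit over spatial cues
                # at the short SOA; valid-invalid is -0.02 (100 ms) / -0.11 (800 ms)
                "neutral@100": 10.51, "valid@100": 9.24, "invalid@100": 9.26,
                "neutral@800": 9.78, "valid@800": 9.725, "invalid@800": 9.835,
            },
            miss_rate=0.0074,
            false_alarm_rate=0.0267,
            pre_target_rate=0.0147,
        )
    raise ValueError(f"unknown experiment tag: {experiment!r}")


@dataclass
class SimulatedDataset:
    """Completed trials plus the generating truth (for recovery tests)."""

    experiment: str
    trials: pd.DataFrame
    truth: GenerativeParams
    seed: int | None = None
    subject_offsets: pd.DataFrame | None = None


def sample_colour_response(target_colour_deg, rho, kappa, rng):
    """Sample colour-wheel click(s) for encoded-or-guessing responses.

    With probability rho the signed error is von Mises(0, kappa) (radians,
    converted to degrees); otherwise the click is uniform on [0, 360).
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    target = np.asarray(target_colour_deg, dtype=float)
    scalar = target.ndim == 0
    target = np.atleast_1d(target)
    n = target.shape[0]
    encoded = rng.random(n) < rho
    err_vm = rad2deg(rng.vonmises(0.0, kappa, size=n))
    # guesses expressed as target + uniform offset: marginally uniform on the
    # wheel, and responses co-rotate with targets under a common shift
    err_guess = rng.uniform(-180.0, 180.0, size=n)
    resp = wrap_deg(target + np.where(encoded, err_vm, err_guess))
    return float(resp[0]) if scalar else resp


def sample_rt(condition, params: GenerativeParams, subject_offset: float, rng, size=None):
    """Lognormal RT: log rt ~ N(rt_log_mean + effect + subject_offset, sd)."""
    if condition not in params.rt_effects:
        raise KeyError(f"unknown condition {condition!r}")
    loc = params.rt_log_mean + params.rt_effects[condition] + subject_offset
    return np.exp(rng.normal(loc, params.rt_log_sd_within, size=size))


def simulate_subject(
    schedule: "_design.TrialSchedule | pd.DataFrame",
    params: GenerativeParams,
    rng: np.random.Generator,
    subject_offsets: dict | None = None,
) -> pd.DataFrame:
    """Fill in responses for one subject's schedule.

    Target trials become misses w.p. ``miss_rate`` (no RT, no colour click),
    pre-target responses w.p. ``pre_target_rate`` (RT uniform in [-SOA, 0)
    relative to target onset, uniform colour click), otherwise hits with a
    lognormal RT and a mixture colour response. Catch trials become false
    alarms w.p. ``false_alarm_rate`` (lognormal RT, uniform click — no
    target colour existed) or correct rejections (no response).
    """
    df = (schedule.trials if isinstance(schedule, _design.TrialSchedule) else schedule).copy()
    offs = subject_offsets or {"rt": 0.0, "rho_logit": 0.0, "log_kappa": 0.0}
    cells = condition_cell(
        df["cue_type"].to_numpy(), df["soa_ms"].to_numpy(), params.experiment
    )
    cells = np.atleast_1d(cells)

    is_target = df["target_present"].to_numpy(dtype=bool)
    n = len(df)
    u = rng.random(n)
    outcome = np.full(n, "", dtype=object)
    # target trials: miss / pre_target / hit
    outcome[is_target & (u < params.miss_rate)] = "miss"
    pre = is_target & (u >= params.miss_rate) & (u < params.miss_rate + params.pre_target_rate)
    outcome[pre] = "pre_target"
    hit = is_target & (outcome == "")
    outcome[hit] = "hit"
    # catch trials: false alarm / correct rejection
    fa = ~is_target & (u < params.false_alarm_rate)
    outcome[fa] = "false_alarm"
    outcome[~is_target & ~fa] = "correct_rejection"

    rt = np.full(n, np.nan)
    resp = np.full(n, np.nan)
    for cell in np.unique(cells):
        m_hit = hit & (cells == cell)
        if m_hit.any():
            rt[m_hit] = sample_rt(cell, params, offs["rt"], rng, size=int(m_hit.sum()))
            logit = np.log(params.rho_by_condition[cell]) - np.log1p(-params.rho_by_condition[cell]) \
                if params.rho_by_condition[cell] < 1.0 else np.inf
            rho_s = 1.0 / (1.0 + np.exp(-(logit + offs["rho_logit"]))) if np.isfinite(logit) else 1.0
            kappa_s = float(np.exp(np.log(params.kappa_by_condition[cell]) + offs["log_kappa"]))
            resp[m_hit] = sample_colour_response(
                df.loc[m_hit, "target_colour_deg"].to_numpy(), rho_s, kappa_s, rng
            )
        m_fa = fa & (cells == cell)
        if m_fa.any():
            rt[m_fa] = sample_rt(cell, params, offs["rt"], rng, size=int(m_fa.sum()))
            resp[m_fa] = rng.uniform(0.0, 360.0, size=int(m_fa.sum()))
    if pre.any():
        soa = df.loc[pre, "soa_ms"].to_numpy(dtype=float)
        rt[pre] = rng.uniform(-soa, 0.0)
        resp[pre] = rng.uniform(0.0, 360.0, size=int(pre.sum()))

    df["outcome"] = outcome
    df["rt_ms"] = rt
    df["response_colour_deg"] = resp
    return df


def simulate_experiment(
    n_subjects: int,
    experiment: str,
    params: GenerativeParams | None = None,
    seed: int = 0,
    n_blocks: int | None = None,
    practice: bool = True,
    counterbalance_arm: str | None = None,
) -> SimulatedDataset:
    """Simulate a full multi-subject experiment.

    Subject-level intercept deviations for RT (log-ms), encoding probability
    (logit) and fidelity (log-kappa) are drawn from ``params.subject_sds``.
    E1 counterbalance arms alternate across subjects. The generating truth
    (including per-subject offsets) is stored for recovery analyses.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    params = params if params is not None else default_params(experiment)
    if n_blocks is None:
        n_blocks = 7 if experiment == "E1" else 8
    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(n_subjects)
    frames, offsets_rows = [], []
    for i, ss in enumerate(subject_seeds):
        rng = np.random.default_rng(ss)
        offs = {
            "rt": rng.normal(0.0, params.subject_sds["rt"]),
            "rho_logit": rng.normal(0.0, params.subject_sds["rho_logit"]),
            "log_kappa": rng.normal(0.0, params.subject_sds["log_kappa"]),
        }
        if counterbalance_arm is None:
            arm = _design.ARM_2_RIGHT if i % 2 == 0 else _design.ARM_2_LEFT
        else:
            arm = counterbalance_arm
        sched = _design.build_session(
            experiment,
            n_blocks=n_blocks,
            practice=practice,
            seed=rng,
            counterbalance_arm=arm,
            subject_id=f"S{i:03d}",
        )
        frames.append(simulate_subject(sched, params, rng, offs))
        offsets_rows.append({"subject_id": f"S{i:03d}", **offs})
    trials = pd.concat(frames, ignore_index=True)
    return SimulatedDataset(
        experiment=experiment,
        trials=trials,
        truth=params,
        seed=seed,
        subject_offsets=pd.DataFrame(offsets_rows),
    )
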