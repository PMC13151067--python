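"""1:1 biosensor kinetics: closed-form sensorgram model, synthetic trace
generation, global multi-concentration fitting, and affinity triage.

The Langmuir 1:1 model in closed form:

* association (t_a ≤ t < t_d):
  ``R(t) = R_eq * (1 - exp(-k_obs * (t - t_a)))`` with
  ``k_obs = k_on * C + k_off`` and ``R_eq = R_max * C / (C + K_D)``,
* dissociation (t ≥ t_d):
  ``R(t) = R(t_d) * exp(-k_off * (t - t_d))``.

Global fitting shares one (k_on, k_off, R_max) triple across all analyte
concentrations, with an optional per-trace baseline offset, and reports
``K_D = k_off / k_on`` with Jacobian-based standard errors.  Alanine-scan
variants are triaged by K_D fold change over the parent peptide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "Sensorgram",
    "KineticFit",
    "model_1to1",
    "simulate_sensorgrams",
    "fit_global_1to1",
    "fold_selectivity",
    "classify_alascan",
    "FOLD_CLASSES",
]


@dataclass(frozen=True)
class Sensorgram:
    """One reference-subtracted trace at a single analyte concentration.

    Times are seconds from the start of the baseline phase; ``t_assoc`` and
    ``t_dissoc`` mark the association and dissociation starts.
    """

    concentration: float        # molar
    time: np.ndarray            # s, strictly increasing
    response: np.ndarray        # nm
    t_assoc: float
    t_dissoc: float
    referenced: bool = True

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("analyte concentration must be positive")
        if len(self.time) != len(self.response):
            raise ValueError("time and response lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not self.t_assoc < self.t_dissoc:
            raise ValueError("association must start before dissociation")


@dataclass
class KineticFit:
    """Globally fitted 1:1 parameters with uncertainty and diagnostics."""

    k_on: float                 # 1/(M s)
    k_off: float                # 1/s
    r_max: float                # nm
    offsets: np.ndarray         # per-trace baseline offsets, nm
    k_d: float                  # M, = k_off / k_on
    rmse: float
    std_errors: dict = field(default_factory=dict)
    converged: bool = True
    n_points: int = 0

    def __post_init__(self) -> None:
        if min(self.k_on, self.k_off, self.r_max) <= 0:
            raise ValueError("kinetic parameters must be positive")
        if abs(self.k_d - self.k_off / self.k_on) > 1e-12 * self.k_d:
            raise ValueError("K_D inconsistent with k_off / k_on")


def model_1to1(
    t: np.ndarray | float,
    concentration: float,
    k_on: float,
    k_off: float,
    r_max: float,
    t_assoc: float = 0.0,
    t_dissoc: float = np.inf,
) -> np.ndarray:
    """Closed-form 1:1 response at times ``t`` (baseline 0 before t_assoc)."""
    if min(k_on, k_off, r_max) <= 0 or concentration <= 0:
        raise ValueError("model parameters and concentration must be positive")
    t = np.asarray(t, dtype=float)
    k_obs = k_on * concentration + k_off
    k_d = k_off / k_on
    r_eq = r_max * concentration / (concentration + k_d)
    r_at_td = r_eq * (1.0 - np.exp(-k_obs * (t_dissoc - t_assoc))) if np.isfinite(t_dissoc) else r_eq

    assoc = r_eq * (1.0 - np.exp(-k_obs * np.maximum(t - t_assoc, 0.0)))
    dissoc = r_at_td * np.exp(-k_off * np.maximum(t - t_dissoc, 0.0))
    out = np.where(t < t_assoc, 0.0, np.where(t < t_dissoc, assoc, dissoc))
    return out if out.ndim else float(out)


def simulate_sensorgrams(
    k_on: float,
    k_off: float,
    r_max: float,
    concentrations: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline_s: float = 300.0,
    assoc_s: float = 210.0,
    dissoc_s: float = 300.0,
    dt: float = 1.0,
) -> list[Sensorgram]:
    """Model traces plus i.i.d. Gaussian noise; the default phase layout is
    a 5 min baseline, 210 s association and 5 min dissociation."""
    if len(concentrations) < 2:
        raise ValueError("at least 2 analyte concentrations are required")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, baseline_s + assoc_s + dissoc_s + dt / 2, dt)
    t_assoc, t_dissoc = baseline_s, baseline_s + assoc_s
    grams = []
    for c in concentrations:
        r = model_1to1(t, c, k_on, k_off, r_max, t_assoc, t_dissoc)
        if noise_sd > 0:
            r = r + rng.normal(0.0, noise_sd, size=len(t))
        grams.append(
            Sensorgram(
                concentration=c,
                time=t.copy(),
                response=np.asarray(r, dtype=float),
                t_assoc=t_assoc,
                t_dissoc=t_dissoc,
            )
        )
    return grams


def _initial_guesses(grams: list[Sensorgram]) -> list[tuple[float, float, float]]:
    """Multi-start seeds: a k_obs linearization estimate plus a coarse
    log-spaced grid as fallback."""
    r_top = max(float(np.max(g.response)) for g in grams)
    r_top = max(r_top, 1e-6)
    guesses: list[tuple[float, float, float]] = []

    # linearization: per-trace k_off from log-linear dissociation decay and
    # k_obs from the association half-rise time, then regress k_obs on C
    k_offs, k_obs_pairs = [], []
    for g in grams:
        dis = (g.time >= g.t_dissoc) & (g.response > 0.05 * r_top)
        if dis.sum() >= 5:
            slope = np.polyfit(g.time[dis], np.log(g.response[dis]), 1)[0]
            if slope < 0:
                k_offs.append(-slope)
        asc = (g.time >= g.t_assoc) & (g.time < g.t_dissoc)
        if asc.sum() >= 5:
            r = g.response[asc]
            plateau = float(np.percentile(r, 95))
            if plateau > 0:
                half = np.argmax(r >= 0.5 * plateau)
                t_half = g.time[asc][half] - g.t_assoc
                if t_half > 0:
                    k_obs_pairs.append((g.concentration, np.log(2.0) / t_half))
    if k_offs and len(k_obs_pairs) >= 2:
        k_off0 = float(np.median(k_offs))
        c_arr = np.array([p[0] for p in k_obs_pairs])
        ko_arr = np.array([p[1] for p in k_obs_pairs])
        k_on0 = float(np.polyfit(c_arr, ko_arr, 1)[0])
        if k_on0 > 0:
            guesses.append((k_on0, k_off0, r_top * 1.2))

    for k_on0 in (1e3, 1e4, 1e5, 1e6):
        for k_off0 in (1e-4, 1e-3, 1e-2, 1e-1):
            guesses.append((k_on0, k_off0, r_top * 1.2))
    return guesses


def fit_global_1to1(
    grams: list[Sensorgram],
    fit_offsets: bool = True,
) -> KineticFit:
    """Least-squares global 1:1 fit over association + dissociation.

    Parameters are optimized in log space (k_on, k_off, R_max strictly
    positive); per-trace baseline offsets are linear nuisance parameters.
    Non-convergence is flagged on the result, never silent.
    """
    if len(grams) < 2:
        raise ValueError("global fitting needs at least 2 traces")
    concs = [g.concentration for g in grams]
    if max(concs) / min(concs) < 4.0:
        raise ValueError("concentrations must span at least 4-fold")

    n_traces = len(grams)
    masks = [(g.time >= g.t_assoc) for g in grams]
    n_points = int(sum(m.sum() for m in masks))

    def residuals(params: np.ndarray) -> np.ndarray:
        k_on, k_off, r_max = np.exp(params[:3])
        offsets = params[3:] if fit_offsets else np.zeros(n_traces)
        res = []
        for g, m, off in zip(grams, masks, offsets):
            pred = model_1to1(
                g.time[m], g.concentration, k_on, k_off, r_max, g.t_assoc, g.t_dissoc
            )
            res.append(pred + off - g.response[m])
        return np.concatenate(res)

    # rank candidate starts by raw cost, refine only the most promising
    starts = []
    for k_on0, k_off0, r_max0 in _initial_guesses(grams):
        x0 = np.concatenate(
            [np.log([k_on0, k_off0, r_max0]), np.zeros(n_traces if fit_offsets else 0)]
        )
        starts.append((float(np.sum(residuals(x0) ** 2)), x0))
    starts.sort(key=lambda s: s[0])

    best = None
    for _, x0 in starts[:3]:
        try:
            sol = least_squares(residuals, x0, method="lm", max_nfev=4000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all fit starts failed")

    k_on, k_off, r_max = np.exp(best.x[:3])
    offsets = best.x[3:] if fit_offsets else np.zeros(n_traces)
    rss = 2.0 * best.cost
    dof = max(n_points - len(best.x), 1)
    rmse = float(np.sqrt(rss / n_points))

    # standard errors via the Jacobian at the optimum (delta method for the
    # log-parametrized kinetic constants)
    std_errors: dict[str, float] = {}
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.inv(jtj) * rss / dof
        log_se = np.sqrt(np.clip(np.diag(cov)[:3], 0, None))
        std_errors = {
            "k_on": float(k_on * log_se[0]),
            "k_off": float(k_off * log_se[1]),
            "r_max": float(r_max * log_se[2]),
        }
        kd = k_off / k_on
        std_errors["k_d"] = float(kd * np.hypot(log_se[0], log_se[1]))
    except np.linalg.LinAlgError:
        pass

    return KineticFit(
        k_on=float(k_on),
        k_off=float(k_off),
        r_max=float(r_max),
        offsets=np.asarray(offsets, dtype=float),
        k_d=float(k_off / k_on),
        rmse=rmse,
        std_errors=std_errors,
        converged=bool(best.success),
        n_points=n_points,
    )


def fold_selectivity(k_d_offtarget: float, k_d_target: float) -> float:
    """Selectivity fold: off-target K_D over target K_D (>1 favors target)."""
    if k_d_offtarget <= 0 or k_d_target <= 0:
        raise ValueError("dissociation constants must be positive")
    return k_d_offtarget / k_d_target


#: affinity-loss classes by K_D fold change of a variant over its parent:
#: neutral < 2, mild 2–4, intermediate (4, 9], essential > 9.
FOLD_CLASSES = ("neutral", "mild", "intermediate", "essential")


def _classify_fold(fold: float) -> str:
    if fold > 9.0:
        return "essential"
    if fold > 4.0:
        return "intermediate"
    if fold >= 2.0:
        return "mild"
    return "neutral"


def classify_alascan(
    parent_kd: float, variant_kds: dict[str, float | None]
) -> pd.DataFrame:
    """Fold-change triage of alanine-scan variants against the parent.

    Boundaries: fold > 9 → essential; 4 < fold ≤ 9 → intermediate;
    2 ≤ fold ≤ 4 → mild; fold < 2 → neutral.  A variant without a
    measurable K_D is flagged ``not-determined``.
    """
    if parent_kd <= 0:
        raise ValueError("parent K_D must be positive")
    rows = []
    for variant, kd in variant_kds.items():
        if kd is None or (isinstance(kd, float) and not np.isfinite(kd)):
            rows.append((variant, np.nan, np.nan, "not-determined"))
            continue
        if kd <= 0:
            raise ValueError(f"variant {variant!r}: K_D must be positive")
        fold = kd / parent_kd
        rows.append((variant, kd, fold, _classify_fold(fold)))
    return pd.DataFrame(rows, columns=["variant", "k_d", "fold_change", "class"])


# ---------------------------------------------------------------------------
# sensorgram CSV dialect (long format: trace_id, phase, t, response, conc)


def sensorgrams_to_frame(grams: list[Sensorgram]) -> pd.DataFrame:
    rows = []
    for i, g in enumerate(grams):
        phase = np.where(
            g.time < g.t_assoc, "baseline",
            np.where(g.time < g.t_dissoc, "association", "dissociation"),
        )
        for t, r, p in zip(g.time, g.response, phase):
            rows.append((i, p, t, r, g.concentration))
    return pd.DataFrame(
        rows, columns=["trace_id", "phase", "t", "response", "concentration"]
    )


def sensorgrams_from_frame(df: pd.DataFrame) -> list[Sensorgram]:
    grams = []
    for _, sub in df.groupby("trace_id"):
        sub = sub.sort_values("t")
        assoc = sub[sub.phase == "association"]["t"]
        dissoc = sub[sub.phase == "dissociation"]["t"]
        if assoc.empty or dissoc.empty:
            raise ValueError("each trace needs association and dissociation phases")
        grams.append(
            Sensorgram(
                concentration=float(sub["concentration"].iloc[0]),
                time=sub["t"].to_numpy(dtype=float),
                response=sub["response"].to_numpy(dtype=float),
                t_assoc=float(assoc.min()),
                t_dissoc=float(dissoc.min()),
            )
        )
    return grams
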