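"""Non-compartmental pharmacokinetic analysis (NCA).

Model-free estimation of the standard exposure parameters from a
concentration-time profile:

* Cmax / Tmax — highest observed concentration and the earliest time it
  occurs;
* AUC0-t — area under the curve to the last observation, by the linear
  trapezoidal rule (a log-down variant, exact on mono-exponential
  decline, is available as ``auc_method="log-down"``);
* lambda_z / t1/2 — terminal elimination rate from a log-linear
  least-squares fit over the best suffix of post-peak points (selected
  by adjusted r-squared, Tmax excluded), t1/2 = ln 2 / lambda_z;
* AUC0-inf — AUC0-t + Clast / lambda_z.

Times are minutes on input (the bioanalytical sampling schedule) and
hours in every reported parameter; concentrations keep their input unit
(typically ng/ml).  Zero (below-quantification) concentrations are kept
in the AUC before the peak and excluded from the terminal regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io

PARAM_ORDER = ["cmax", "tmax", "t_half", "auc_0_t", "auc_0_inf"]


class TerminalPhaseError(ValueError):
    """Terminal elimination phase not estimable from this profile."""


@dataclass(frozen=True)
class ConcentrationProfile:
    """One subject's concentration-time course (times in minutes)."""
    subject_id: str
    times: tuple
    concs: tuple

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concs, dtype=float)
        if t.size != c.size:
            raise ValueError("times and concs must have equal length")
        if t.size < 3:
            raise ValueError("a profile needs at least 3 points")
        if (np.diff(t) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (c < 0).any():
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "times", tuple(t))
        object.__setattr__(self, "concs", tuple(c))

    @property
    def times_h(self) -> np.ndarray:
        return np.asarray(self.times) / 60.0

    @property
    def conc_array(self) -> np.ndarray:
        return np.asarray(self.concs)


@dataclass(frozen=True)
class PKParameters:
    """The five reported NCA parameters plus fit diagnostics.

    tmax and t_half in hours; auc in conc * hours; lambda_z in 1/hour.
    ``quantifiable`` is False for an all-zero profile, in which case the
    numeric fields are NaN.
    """
    cmax: float
    tmax: float
    t_half: float
    auc_0_t: float
    auc_0_inf: float
    lambda_z: float
    r_squared_terminal: float
    n_terminal_points: int
    quantifiable: bool = True


def compute_cmax_tmax(profile: ConcentrationProfile) -> tuple[float, float]:
    """(Cmax, Tmax in hours); earliest time wins on ties.

    An all-zero profile returns (0.0, nan) — no quantifiable exposure.
    """
    c = profile.conc_array
    if (c == 0).all():
        return 0.0, math.nan
    i = int(np.argmax(c))  # argmax returns the first maximum
    return float(c[i]), float(profile.times_h[i])


def compute_auc_trapezoid(profile: ConcentrationProfile, method: str = "linear") -> float:
    """AUC from the first to the last observation, in conc * hours.

    ``linear`` applies the trapezoid everywhere; ``log-down`` uses the
    logarithmic trapezoid on strictly declining positive segments (exact
    for exponential decline) and the linear rule elsewhere.
    """
    t = profile.times_h
    c = profile.conc_array
    if method == "linear":
        return float(np.trapezoid(c, t))
    if method != "log-down":
        raise ValueError(f"unknown AUC method {method!r}")
    total = 0.0
    for i in range(len(t) - 1):
        c1, c2, dt = c[i], c[i + 1], t[i + 1] - t[i]
        if c1 > c2 > 0:
            total += (c1 - c2) * dt / math.log(c1 / c2)
        else:
            total += (c1 + c2) * dt / 2.0
    return float(total)


def _adj_r2(r2: float, n: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def fit_terminal_slope(profile: ConcentrationProfile, min_points: int = 3
                       ) -> tuple[float, float, float, int]:
    """Estimate (lambda_z /h, t_half h, r_squared, points_used).

    Candidate point sets are the suffixes of the strictly-post-peak
    positive observations, length >= ``min_points``; the suffix with the
    highest adjusted r-squared wins (ties go to more points, the
    conventional NCA rule).  Raises :class:`TerminalPhaseError` when no
    suffix yields a positive elimination slope.
    """
    if min_points < 3:
        raise ValueError("min_points must be >= 3")
    c = profile.conc_array
    t = profile.times_h
    if (c == 0).all():
        raise TerminalPhaseError("all-zero profile")
    i_max = int(np.argmax(c))
    mask = (np.arange(len(c)) > i_max) & (c > 0)
    idx = np.flatnonzero(mask)
    if idx.size < min_points:
        raise TerminalPhaseError(
            f"only {idx.size} positive post-peak points; need >= {min_points}")
    best = None
    for start in range(idx.size - min_points + 1):
        sel = idx[start:]
        x, y = t[sel], np.log(c[sel])
        slope, intercept = np.polyfit(x, y, 1)
        ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        adj = _adj_r2(r2, sel.size)
        # strict ">" keeps the longest suffix on exact ties (scanned long->short)
        if best is None or adj > best[0] + 1e-12:
            best = (adj, r2, slope, sel.size)
    _, r2, slope, n_used = best
    lam = -slope
    if lam <= 0:
        raise TerminalPhaseError("nonpositive terminal slope: no elimination phase")
    return float(lam), float(math.log(2) / lam), float(r2), int(n_used)


def extrapolate_auc_inf(auc_0_t: float, c_last: float, lambda_z: float) -> float:
    """AUC0-inf = AUC0-t + Clast / lambda_z (lambda_z must be positive)."""
    if lambda_z <= 0:
        raise ValueError("lambda_z must be positive for extrapolation")
    if c_last < 0:
        raise ValueError("c_last must be >= 0")
    return auc_0_t + c_last / lambda_z


def analyze_profile(profile: ConcentrationProfile, auc_method: str = "linear",
                    min_points: int = 3) -> PKParameters:
    """All five parameters for one subject."""
    cmax, tmax = compute_cmax_tmax(profile)
    if cmax == 0.0:
        nan = math.nan
        return PKParameters(nan, nan, nan, nan, nan, nan, nan, 0, quantifiable=False)
    auc_t = compute_auc_trapezoid(profile, method=auc_method)
    lam, t_half, r2, n_used = fit_terminal_slope(profile, min_points=min_points)
    c = profile.conc_array
    c_last = float(c[np.flatnonzero(c > 0)[-1]])
    auc_inf = extrapolate_auc_inf(auc_t, c_last, lam)
    return PKParameters(cmax, tmax, t_half, auc_t, auc_inf, lam, r2, n_used)


# ---------------------------------------------------------------------------
# tables

def profiles_from_table(df: pd.DataFrame) -> list[ConcentrationProfile]:
    """Split a (subject, time_min, conc) table into per-subject profiles."""
    out = []
    for subject, grp in df.groupby("subject", sort=True):
        grp = grp.sort_values("time_min")
        out.append(ConcentrationProfile(str(subject),
                                        tuple(grp["time_min"]), tuple(grp["conc"])))
    return out


def summarize_pk(profiles_by_compound: dict, auc_method: str = "linear") -> pd.DataFrame:
    """Mean +/- sample SD of each parameter per compound.

    ``profiles_by_compound`` maps compound id -> list of profiles.  The
    output has one row per compound and, per parameter in the
    conventional report order (Cmax, Tmax, t1/2, AUC0-t, AUC0-inf), a
    ``_mean`` and ``_sd`` column.  With a single subject the SD is NaN
    (absent), never zero.
    """
    rows = {}
    for compound, profiles in sorted(profiles_by_compound.items()):
        params = [analyze_profile(p, auc_method=auc_method) for p in profiles]
        params = [p for p in params if p.quantifiable]
        if not params:
            raise ValueError(f"compound {compound!r}: no quantifiable profiles")
        row = {}
        for name in PARAM_ORDER:
            vals = pd.Series([getattr(p, name) for p in params], dtype=float)
            row[f"{name}_mean"] = vals.mean()
            row[f"{name}_sd"] = vals.std(ddof=1)  # NaN for n=1
        row["n_subjects"] = len(params)
        rows[compound] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "compound"
    return df


def run_nca(conc_csv, out_tsv=None, auc_method: str = "linear",
            per_subject_tsv=None) -> pd.DataFrame:
    """File-level entry point: concentration CSV in, summary TSV out.

    The CSV may carry an optional ``compound`` column; otherwise all
    subjects are summarized as a single compound "all".
    """
    df = io.read_concentrations(conc_csv)
    if "compound" in df.columns:
        groups = {cid: profiles_from_table(g) for cid, g in df.groupby("compound")}
    else:
        groups = {"all": profiles_from_table(df)}
    if per_subject_tsv is not None:
        recs = []
        for cid, profiles in sorted(groups.items()):
            for p in profiles:
                pk = analyze_profile(p, auc_method=auc_method)
                recs.append({"compound": cid, "subject": p.subject_id,
                             **{k: getattr(pk, k) for k in PARAM_ORDER},
                             "lambda_z": pk.lambda_z,
                             "r_squared_terminal": pk.r_squared_terminal})
        pd.DataFrame(recs).to_csv(per_subject_tsv, sep="\t", index=False)
    summary = summarize_pk(groups, auc_method=auc_method)
    if out_tsv is not None:
        summary.to_csv(out_tsv, sep="\t")
    return summary
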