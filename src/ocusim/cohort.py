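"""Synthetic paired pre/post femto-LASIK cohort generator and statistics.

The generator emulates the marginal statistics of the modeled 134-eye
study population: pre-operative parameters are truncated Gaussians
independent of the initial myopia S, and post-operative corneal parameters
follow a conditional-Gaussian link

    post = mu_post + beta_S (S - mean S) + kappa (pre - mu_pre) + eps

whose S-slope beta_S is solved in closed form so that the post-operative
marginal mean and SD reproduce the published values exactly in expectation
while the surgically induced changes of the anterior cornea (radius,
asphericity, high-order RMS) correlate with S; the posterior cornea
changes without any S dependence.  Lens, vitreous and retina parameters
are carried over unchanged from pre to post.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .eye import BiometryRecord, CornealSurfaceSpec
from .surfaces import N_TERMS, ZernikeCoefficientSet, osa_double_indices

__all__ = [
    "ParamLink",
    "CohortConfig",
    "CohortRecord",
    "sample_cohort",
    "assign_group",
    "correlate",
    "group_summary",
    "cohort_to_jsonl",
    "cohort_from_jsonl",
    "DEFAULT_PARAMS",
]

_INDICES = osa_double_indices()
_LOW = np.array([i <= 2 for i, _ in _INDICES])
N_LOW = int(_LOW.sum())  # 6 terms, orders 0-2
N_HIGH = N_TERMS - N_LOW  # 22 terms, orders 3-6


@dataclass
class ParamLink:
    """Marginal statistics and pre->post link for one biometry parameter.

    ``beta_sign`` is -1/0/+1: the sign of the linear-in-S surgical change;
    its magnitude is solved from the published pre/post SDs, kappa, the
    residual SD and the S variance so the post marginal SD is reproduced.
    """

    mu_pre: float
    sd_pre: float
    mu_post: float
    sd_post: float
    kappa: float = 1.0
    sigma_eps: float = 0.0
    beta_sign: int = 0
    lo: float = -np.inf
    hi: float = np.inf
    n_sigma: float = 4.0

    def pre_bounds(self) -> tuple[float, float]:
        return (max(self.lo, self.mu_pre - self.n_sigma * self.sd_pre),
                min(self.hi, self.mu_pre + self.n_sigma * self.sd_pre))

    def post_bounds(self) -> tuple[float, float]:
        return (max(self.lo, self.mu_post - self.n_sigma * self.sd_post),
                min(self.hi, self.mu_post + self.n_sigma * self.sd_post))

    def beta(self, var_s: float) -> float:
        """Closed-form S slope reproducing the post-operative SD."""
        if self.beta_sign == 0:
            return 0.0
        resid = self.sd_post**2 - (self.kappa * self.sd_pre)**2 - self.sigma_eps**2
        if resid <= 0:
            raise ValueError(
                f"infeasible link: kappa/sigma_eps leave no S-driven variance "
                f"(sd_post={self.sd_post})")
        return self.beta_sign * math.sqrt(resid / var_s)

    def eps_sd(self) -> float:
        """Residual SD (recomputed for S-independent links)."""
        if self.beta_sign == 0:
            resid = self.sd_post**2 - (self.kappa * self.sd_pre)**2
            if resid < 0:
                raise ValueError("infeasible link: kappa too large for the post SD")
            return math.sqrt(resid)
        return self.sigma_eps


# Published cohort marginals (134 eyes, mean +/- SD) used as defaults.
DEFAULT_PARAMS: dict[str, ParamLink] = {
    # anterior cornea: flattened, more oblate, more irregular; all three
    # changes correlate with initial myopia (more myopic -> larger change)
    "ant_R": ParamLink(7.77, 0.25, 8.56, 0.43, kappa=1.0, sigma_eps=0.08,
                       beta_sign=-1, lo=5.0, hi=12.0),
    "ant_Q": ParamLink(-0.28, 0.11, 0.63, 0.44, kappa=1.0, sigma_eps=0.15,
                       beta_sign=-1, lo=-2.0, hi=3.0),
    "ant_LO": ParamLink(0.87, 0.27, 0.80, 0.36, kappa=0.8, lo=0.02, hi=3.0),
    "ant_HO": ParamLink(0.09, 0.02, 0.15, 0.05, kappa=1.0, sigma_eps=0.015,
                        beta_sign=-1, lo=0.005, hi=1.0),
    # posterior cornea: essentially unchanged, no S dependence
    "post_R": ParamLink(6.35, 0.23, 6.38, 0.22, kappa=0.9 * 0.22 / 0.23, lo=4.5, hi=9.0),
    "post_Q": ParamLink(-0.31, 0.12, -0.26, 0.12, kappa=0.9, lo=-2.0, hi=2.0),
    "post_LO": ParamLink(0.53, 0.09, 0.53, 0.10, kappa=0.9 * 0.10 / 0.09, lo=0.02, hi=3.0),
    "post_HO": ParamLink(0.04, 0.01, 0.05, 0.01, kappa=0.9, lo=0.002, hi=1.0),
    # ablation: central cornea thinned, more so for higher myopia
    "CCT": ParamLink(0.54, 0.03, 0.45, 0.04, kappa=1.0, sigma_eps=0.011,
                     beta_sign=+1, lo=0.35, hi=0.75),
    "T_AC": ParamLink(3.39, 0.28, 3.16, 0.27, kappa=0.9 * 0.27 / 0.28, lo=1.8, hi=5.0),
    # unchanged by surgery (post stats identical by construction)
    "T_L": ParamLink(3.79, 0.42, 3.79, 0.42, kappa=1.0, lo=2.5, hi=5.5),
    "T_V": ParamLink(17.59, 0.89, 17.59, 0.89, kappa=1.0, lo=13.0, hi=22.0),
}

_SHARED = ("T_L", "T_V")  # identical pre/post per eye


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort generator."""

    n: int = 134
    seed: int = 42
    s_range: tuple[float, float] = (-10.5, -1.25)
    params: dict = field(default_factory=lambda: {k: v for k, v in DEFAULT_PARAMS.items()})
    pattern_blend: float = 1.0  # fresh-direction weight when re-drawing post Zernikes
    max_resample: int = 200

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort size must be >= 2")
        lo, hi = self.s_range
        if not (lo < hi <= 0):
            raise ValueError("S range must be negative with lo < hi")
        for name, p in self.params.items():
            if p.sd_pre < 0 or p.sd_post < 0:
                raise ValueError(f"{name}: SDs must be non-negative")
            if p.lo >= p.hi:
                raise ValueError(f"{name}: bad truncation bounds")

    @property
    def s_var(self) -> float:
        lo, hi = self.s_range
        return (hi - lo) ** 2 / 12.0

    @property
    def s_mean(self) -> float:
        return 0.5 * sum(self.s_range)

    def as_dict(self) -> dict:
        d = {"n": self.n, "seed": self.seed, "s_range": list(self.s_range),
             "pattern_blend": self.pattern_blend, "params": {}}
        for k, p in self.params.items():
            d["params"][k] = {f: getattr(p, f) for f in
                              ("mu_pre", "sd_pre", "mu_post", "sd_post", "kappa",
                               "sigma_eps", "beta_sign", "lo", "hi", "n_sigma")}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        params = {k: ParamLink(**v) for k, v in d.get("params", {}).items()} \
            or {k: v for k, v in DEFAULT_PARAMS.items()}
        return cls(n=int(d.get("n", 134)), seed=int(d.get("seed", 42)),
                   s_range=tuple(d.get("s_range", (-10.5, -1.25))),
                   params=params,
                   pattern_blend=float(d.get("pattern_blend", 1.0)))


@dataclass
class CohortRecord:
    """Paired pre/post biometry of one synthetic eye."""

    id: str
    S: float
    pre: BiometryRecord
    post: BiometryRecord
    group: str

    def as_dict(self) -> dict:
        return {"id": self.id, "S": self.S, "group": self.group,
                "pre": self.pre.as_dict(), "post": self.post.as_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "CohortRecord":
        return cls(id=d["id"], S=float(d["S"]), group=d["group"],
                   pre=BiometryRecord.from_dict(d["pre"]),
                   post=BiometryRecord.from_dict(d["post"]))


def assign_group(S: float) -> str:
    """Initial-myopia group: mild (-3 <= S < 0), medium (-6 <= S < -3), high (S < -6).

    Boundary values go to the more myopic group.
    """
    if S > 0:
        raise ValueError(f"S must be <= 0 for myopia grouping, got {S}")
    if S > -3.0:
        return "mild"
    if S > -6.0:
        return "medium"
    return "high"


def _truncated_normal(rng: np.random.Generator, mu: float, sd: float,
                      lo: float, hi: float, size: int, max_iter: int = 500
                      ) -> np.ndarray:
    if sd == 0:
        return np.full(size, mu)
    out = rng.normal(mu, sd, size)
    for _ in range(max_iter):
        bad = (out < lo) | (out > hi)
        if not np.any(bad):
            break
        out[bad] = rng.normal(mu, sd, int(bad.sum()))
    return np.clip(out, lo, hi)


def _unit_vector(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.standard_normal(dim)
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.eye(dim)[0]


def _zernike_from_bands(lo_dir: np.ndarray, hi_dir: np.ndarray,
                        lo_rms: float, hi_rms: float) -> ZernikeCoefficientSet:
    values = np.zeros(N_TERMS)
    values[_LOW] = lo_dir * lo_rms
    values[~_LOW] = hi_dir * hi_rms
    return ZernikeCoefficientSet(values)


def _stratified_uniform(rng: np.random.Generator, lo: float, hi: float, n: int
                        ) -> np.ndarray:
    """Uniform sample with one draw per equal-width stratum, shuffled."""
    u = (np.arange(n) + rng.random(n)) / n
    s = lo + u * (hi - lo)
    rng.shuffle(s)
    return s


def sample_cohort(cfg: CohortConfig = CohortConfig()) -> list[CohortRecord]:
    """Draw a fully reproducible synthetic pre/post cohort."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    lo_s, hi_s = cfg.s_range
    S = _stratified_uniform(rng, lo_s, hi_s, n)

    # canonical (sorted) parameter order so the stream of random draws does
    # not depend on dict insertion order (configs survive JSON round trips)
    names = sorted(cfg.params)
    pre_vals: dict[str, np.ndarray] = {}
    for name in names:
        p = cfg.params[name]
        blo, bhi = p.pre_bounds()
        pre_vals[name] = _truncated_normal(rng, p.mu_pre, p.sd_pre, blo, bhi, n)

    post_vals: dict[str, np.ndarray] = {}
    for name in names:
        p = cfg.params[name]
        if name in _SHARED:
            post_vals[name] = pre_vals[name].copy()
            continue
        beta = p.beta(cfg.s_var)
        sd_eps = p.eps_sd()
        base = (p.mu_post + beta * (S - cfg.s_mean)
                + p.kappa * (pre_vals[name] - p.mu_pre))
        eps = rng.normal(0.0, sd_eps, n) if sd_eps > 0 else np.zeros(n)
        v = base + eps
        blo, bhi = p.post_bounds()
        # resample the residual only, holding S and the pre value fixed,
        # until truncation and pairing constraints hold
        for _ in range(cfg.max_resample):
            bad = (v < blo) | (v > bhi)
            if name == "ant_R":
                bad |= v <= pre_vals[name]
            elif name == "CCT":
                bad |= v >= pre_vals[name]
            if not np.any(bad):
                break
            if sd_eps == 0:
                break
            v[bad] = base[bad] + rng.normal(0.0, sd_eps, int(bad.sum()))
        v = np.clip(v, blo, bhi)
        if name == "ant_R":
            v = np.maximum(v, pre_vals[name] + 1e-3)
        elif name == "CCT":
            v = np.minimum(v, pre_vals[name] - 1e-3)
        post_vals[name] = v

    records = []
    for k in range(n):
        lo_dir_a = _unit_vector(rng, N_LOW)
        hi_dir_a = _unit_vector(rng, N_HIGH)
        lo_dir_p = _unit_vector(rng, N_LOW)
        hi_dir_p = _unit_vector(rng, N_HIGH)

        def _blend(d0, dim):
            fresh = _unit_vector(rng, dim)
            v = d0 + cfg.pattern_blend * fresh
            nv = np.linalg.norm(v)
            return v / nv if nv > 0 else d0

        lo_dir_a2 = _blend(lo_dir_a, N_LOW)
        hi_dir_a2 = _blend(hi_dir_a, N_HIGH)
        lo_dir_p2 = _blend(lo_dir_p, N_LOW)
        hi_dir_p2 = _blend(hi_dir_p, N_HIGH)

        eye_id = f"eye-{k:04d}"
        pre = BiometryRecord(
            S=float(S[k]),
            anterior=CornealSurfaceSpec(
                R=float(pre_vals["ant_R"][k]), Q=float(pre_vals["ant_Q"][k]),
                zernike=_zernike_from_bands(lo_dir_a, hi_dir_a,
                                            pre_vals["ant_LO"][k], pre_vals["ant_HO"][k])),
            posterior=CornealSurfaceSpec(
                R=float(pre_vals["post_R"][k]), Q=float(pre_vals["post_Q"][k]),
                zernike=_zernike_from_bands(lo_dir_p, hi_dir_p,
                                            pre_vals["post_LO"][k], pre_vals["post_HO"][k])),
            CCT=float(pre_vals["CCT"][k]), T_AC=float(pre_vals["T_AC"][k]),
            T_L=float(pre_vals["T_L"][k]), T_V=float(pre_vals["T_V"][k]),
            epoch="pre", eye_id=eye_id,
        )
        post = BiometryRecord(
            S=float(S[k]),
            anterior=CornealSurfaceSpec(
                R=float(post_vals["ant_R"][k]), Q=float(post_vals["ant_Q"][k]),
                zernike=_zernike_from_bands(lo_dir_a2, hi_dir_a2,
                                            post_vals["ant_LO"][k], post_vals["ant_HO"][k])),
            posterior=CornealSurfaceSpec(
                R=float(post_vals["post_R"][k]), Q=float(post_vals["post_Q"][k]),
                zernike=_zernike_from_bands(lo_dir_p2, hi_dir_p2,
                                            post_vals["post_LO"][k], post_vals["post_HO"][k])),
            CCT=float(post_vals["CCT"][k]), T_AC=float(post_vals["T_AC"][k]),
            T_L=float(post_vals["T_L"][k]), T_V=float(post_vals["T_V"][k]),
            epoch="post", eye_id=eye_id,
        )
        records.append(CohortRecord(id=eye_id, S=float(S[k]), pre=pre, post=post,
                                    group=assign_group(float(S[k]))))
    return records


class UndefinedCorrelationError(ValueError):
    pass


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and two-sided P via the t transform with n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(np.sum(dx * dx))
    syy = float(np.sum(dy * dy))
    if sxx == 0 or syy == 0:
        raise UndefinedCorrelationError("zero variance in one of the inputs")
    r = float(np.sum(dx * dy)) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(_sps.t.sf(abs(t), n - 2))
    return r, p


def group_summary(reports, records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Mean +/- SD of every metric per (group, epoch, field, pupil).

    ``reports`` is a list of QualityReport (or their concatenated tidy
    DataFrame); groups come from the matched cohort records.  Empty groups
    yield flagged rows (n_eyes = 0) rather than an error.
    """
    if isinstance(reports, pd.DataFrame):
        df = reports.copy()
    else:
        df = pd.concat([r.df for r in reports], ignore_index=True)
    group_of = {r.id: r.group for r in records}
    missing = set(df.eye_id) - set(group_of)
    if missing:
        raise ValueError(f"reports contain unmatched eye ids: {sorted(missing)[:5]}")
    df["group"] = df.eye_id.map(group_of)
    out = (df.groupby(["group", "epoch", "field_deg", "pupil_mm", "metric"],
                      as_index=False)
             .agg(mean=("value", "mean"), sd=("value", lambda v: float(np.std(v, ddof=0))),
                  n_eyes=("eye_id", "nunique")))
    present = set(out.group)
    flags = [g for g in ("mild", "medium", "high") if g not in present]
    if flags:
        pad = pd.DataFrame([{"group": g, "epoch": "", "field_deg": np.nan,
                             "pupil_mm": np.nan, "metric": "EMPTY_GROUP",
                             "mean": np.nan, "sd": np.nan, "n_eyes": 0}
                            for g in flags])
        out = pd.concat([out, pad], ignore_index=True)
    return out


def cohort_to_jsonl(records: Sequence[CohortRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(r.as_dict(), sort_keys=True) + "\n")


def cohort_from_jsonl(path) -> list[CohortRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(CohortRecord.from_dict(json.loads(line)))
    return out
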