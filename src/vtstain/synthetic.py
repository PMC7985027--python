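"""Ground-truth-bearing generators for every pipeline stage.

Three generators emulate the study's data with known truth so each estimator
can be validated against planted parameters:

* :func:`make_stain_pair` — paired pseudo-H&E / pseudo-trichrome slides
  related by a known, stored per-pixel affine palette map (plus a blue
  fibrosis recolouring whose extent is monotone in the true stage), so
  translation error has an exact oracle;
* :func:`simulate_rater_stages` — rater staging tables drawn from the
  concordance model's own generative process (cumulative-logit with rater
  intercept/slope bias and correlated case random effects), with interval
  reports and a second real-staging round;
* :func:`simulate_clinical` — serology monotone in true stage plus noise, and
  exponential event times whose hazard scales with stage, with independent
  censoring calibrated to a target censor fraction.

Every generator is a pure function of its seed and spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import expit

from .tiling import SlideImage
from .turing import TuringResponse

# ---------------------------------------------------------------------------
# pseudo-stain image pairs
# ---------------------------------------------------------------------------

# Palette map: trichrome ~= A @ he + c per pixel; fibrosis pixels get a blue
# recolouring instead.  Rows of A sum below 1 so white tissue background stays
# light after mapping.
PALETTE_A = np.array([[0.70, 0.15, 0.10],
                      [0.10, 0.65, 0.15],
                      [0.05, 0.25, 0.65]])
PALETTE_C = np.array([10.0, 12.0, 18.0])
FIB_A = np.array([[0.20, 0.05, 0.05],
                  [0.05, 0.25, 0.05],
                  [0.10, 0.10, 0.55]])
FIB_C = np.array([30.0, 45.0, 120.0])


@dataclass
class SyntheticSlideSpec:
    """Specification for one paired pseudo-stain slide."""

    seed: int = 0
    dims: tuple[int, int] = (512, 512)
    true_stage: int = 2
    fibrosis_fraction: float | None = None
    whitespace_layout: str = "none"
    slide_id: str = "synthetic"

    def __post_init__(self) -> None:
        if not 0 <= self.true_stage <= 4:
            raise ValueError("true_stage must lie in 0..4")
        if self.whitespace_layout not in ("none", "border", "blocks"):
            raise ValueError("whitespace_layout must be none|border|blocks")
        if self.fibrosis_fraction is None:
            # monotone in stage: no fibrous texture at F0, ~40% of tissue at F4
            self.fibrosis_fraction = 0.10 * self.true_stage
        if not 0.0 <= self.fibrosis_fraction <= 1.0:
            raise ValueError("fibrosis_fraction must lie in [0, 1]")


def apply_transform_key(key: dict, he_pixels: np.ndarray) -> np.ndarray:
    """Apply the stored palette map to pseudo-H&E pixels (the exact oracle)."""
    he = he_pixels.astype(np.float64)
    base = he @ key["A"].T + key["c"]
    fib = he @ key["A_fib"].T + key["c_fib"]
    out = np.where(key["fibrosis_mask"][..., None], fib, base)
    out = np.where(key["whitespace_mask"][..., None], he, out)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def make_stain_pair(spec: SyntheticSlideSpec) -> tuple[SlideImage, SlideImage, dict]:
    """Paired pseudo-H&E and pseudo-trichrome slides plus the exact transform key.

    A shared band-limited tissue texture with blob nuclei is rendered in a
    pink/purple H&E palette; the trichrome applies the stored affine palette
    map, with a blue recolouring on the fibrosis mask whose area fraction is
    monotone in the true stage.  Whitespace regions are near-white in both
    stains.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.dims

    texture = gaussian_filter(rng.normal(size=(h, w)), sigma=6)
    texture = (texture - texture.min()) / max(1e-12, float(np.ptp(texture)))
    nuclei_field = gaussian_filter(rng.normal(size=(h, w)), sigma=2)
    nuclei = nuclei_field > np.quantile(nuclei_field, 0.92)

    whitespace = np.zeros((h, w), dtype=bool)
    if spec.whitespace_layout == "border":
        m = max(4, min(h, w) // 8)
        whitespace[:m] = whitespace[-m:] = True
        whitespace[:, :m] = whitespace[:, -m:] = True
    elif spec.whitespace_layout == "blocks":
        bh, bw = h // 4, w // 4
        whitespace[:bh, :bw] = True
        whitespace[-bh:, -bw:] = True
    tissue = ~whitespace

    fib_field = gaussian_filter(rng.normal(size=(h, w)), sigma=8)
    fibrosis = np.zeros((h, w), dtype=bool)
    if spec.fibrosis_fraction > 0 and tissue.any():
        thresh = np.quantile(fib_field[tissue], 1.0 - spec.fibrosis_fraction)
        fibrosis = (fib_field >= thresh) & tissue

    he = np.empty((h, w, 3), dtype=np.float64)
    pink = np.array([235.0, 160.0, 195.0])
    purple = np.array([110.0, 70.0, 150.0])
    shade = 0.75 + 0.25 * texture
    he[:] = pink * shade[..., None]
    he[nuclei] = purple * (0.8 + 0.2 * texture[nuclei, None])
    he += rng.normal(0, 3.0, size=he.shape)
    he[whitespace] = 250.0 + rng.normal(0, 1.5, size=(int(whitespace.sum()), 3))
    he = np.clip(np.rint(he), 0, 255).astype(np.uint8)

    key = {"A": PALETTE_A, "c": PALETTE_C, "A_fib": FIB_A, "c_fib": FIB_C,
           "fibrosis_mask": fibrosis, "tissue_mask": tissue,
           "whitespace_mask": whitespace, "true_stage": spec.true_stage}
    tri = apply_transform_key(key, he)
    he_slide = SlideImage(he, f"{spec.slide_id}_he", "HE")
    tri_slide = SlideImage(tri, f"{spec.slide_id}_tri", "trichrome")
    return he_slide, tri_slide, key


# ---------------------------------------------------------------------------
# rater staging tables
# ---------------------------------------------------------------------------

@dataclass
class RaterSimSpec:
    """Generative spec mirroring the concordance model.

    Defaults are the study conditions: 280 cases staged by 4 raters, two real
    staging rounds plus virtual staging, 15% interval reports, and rater
    intercept/slope biases of the order the concordance model is built to
    absorb.  The monotonic coefficient ``b=6`` with cutpoints at
    ``b*(k-0.5)/4`` centres each real stage on its own virtual category, so
    real and virtual stages agree strongly but not perfectly.
    """

    n_cases: int = 280
    n_raters: int = 4
    kappa: tuple = (0.75, 2.25, 3.75, 5.25)
    b: float = 6.0
    zeta: tuple = (0.25, 0.25, 0.25, 0.25)
    alpha: tuple = (0.0, 0.4, -0.3, 0.5)
    b_offset: tuple = (0.0, -0.5, 0.4, 0.6)
    sd_u0: float = 0.7
    sd_u1: float = 0.4
    rho_u: float = 0.3
    interval_report_prob: float = 0.15
    retest_noise: float = 0.5
    latent_scale: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        kappa = np.asarray(self.kappa, dtype=float)
        if (np.diff(kappa) <= 0).any():
            raise ValueError("kappa must be strictly increasing")
        zeta = np.asarray(self.zeta, dtype=float)
        if zeta.shape != (4,) or (zeta < 0).any() or abs(zeta.sum() - 1) > 1e-8:
            raise ValueError("zeta must be a length-4 simplex")
        if not 0.0 <= self.interval_report_prob <= 1.0:
            raise ValueError("interval_report_prob must lie in [0, 1]")
        if len(self.alpha) != self.n_raters or len(self.b_offset) != self.n_raters:
            raise ValueError("alpha and b_offset must have one entry per rater")


def _draw_cumulative_logit(eta: np.ndarray, kappa: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    """Ordinal draws: latent logistic noise against the ordered cutpoints."""
    latent = eta + rng.logistic(size=np.shape(eta))
    return np.digitize(latent, kappa)


def simulate_rater_stages(spec: RaterSimSpec) -> tuple[pd.DataFrame, dict]:
    """Staging table (real tests 1 and 2 plus virtual) with planted truth.

    Real stages per rater/test come from a cumulative-logit read of a latent
    case severity; virtual stages are then drawn *conditionally on the
    observed real stage* from the concordance model itself (rater intercepts
    and monotonic-slope offsets, correlated case random intercept and
    test-slope), so fitting the model to this table is a true
    self-consistency test.  With probability ``interval_report_prob`` an
    observation is widened to the interval ``[stage-1, stage]`` (floored at
    0), mirroring reported staging uncertainty; the upper bound of a widened
    report is the originally drawn stage.

    Returns the long staging table and a truth dict with the planted
    parameters, per-case true stages and random effects.
    """
    rng = np.random.default_rng(spec.seed)
    n, R = spec.n_cases, spec.n_raters
    kappa = np.asarray(spec.kappa, dtype=float)
    zeta = np.asarray(spec.zeta, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(zeta)])

    severity = rng.normal(0.0, 1.0, size=n)
    true_cuts = np.array([-1.5, -0.5, 0.5, 1.5])
    true_stage = np.digitize(severity, true_cuts)

    # correlated case random effects (intercept, test slope)
    L = np.array([[spec.sd_u0, 0.0],
                  [spec.sd_u1 * spec.rho_u, spec.sd_u1 * np.sqrt(1 - spec.rho_u ** 2)]])
    u = rng.normal(size=(n, 2)) @ L.T

    # real stages: latent severity read off through rater-independent cutpoints,
    # with fresh logistic noise per rater/test and extra retest jitter at test 2
    real_kappa = spec.latent_scale * true_cuts
    records = []
    real_stage = np.zeros((n, R, 2), dtype=int)
    for r in range(R):
        for t in (0, 1):
            eta_real = spec.latent_scale * severity
            if t == 1:
                eta_real = eta_real + spec.retest_noise * rng.normal(size=n)
            real_stage[:, r, t] = _draw_cumulative_logit(eta_real, real_kappa, rng)

    # virtual stages: the concordance model's own generative process, one draw
    # per (case, rater, test) conditioned on that row's real stage
    virtual_stage = np.zeros((n, R, 2), dtype=int)
    for r in range(R):
        for t in (0, 1):
            eta = (spec.alpha[r]
                   + (spec.b + spec.b_offset[r]) * cum[real_stage[:, r, t]]
                   + u[:, 0] + u[:, 1] * t)
            virtual_stage[:, r, t] = _draw_cumulative_logit(eta, kappa, rng)

    def emit(case, rater, modality, test_index, stage):
        widen = rng.uniform() < spec.interval_report_prob
        low = max(stage - 1, 0) if widen else stage
        records.append({"case_id": f"C{case:04d}", "rater_id": f"R{rater + 1}",
                        "modality": modality, "test_index": test_index,
                        "stage_low": int(low), "stage_high": int(stage)})

    for case in range(n):
        for r in range(R):
            for t in (0, 1):
                emit(case, r, "real", t + 1, int(real_stage[case, r, t]))
                emit(case, r, "virtual", t + 1, int(virtual_stage[case, r, t]))

    staging = pd.DataFrame.from_records(records)
    truth = {"true_stage": true_stage, "severity": severity, "u": u,
             "kappa": kappa, "b": spec.b, "zeta": zeta,
             "alpha": np.asarray(spec.alpha, dtype=float),
             "b_offset": np.asarray(spec.b_offset, dtype=float),
             "sd_u0": spec.sd_u0, "sd_u1": spec.sd_u1, "rho_u": spec.rho_u,
             "cases": [f"C{i:04d}" for i in range(n)],
             "raters": [f"R{r + 1}" for r in range(R)]}
    return staging, truth


# ---------------------------------------------------------------------------
# clinical records
# ---------------------------------------------------------------------------

#: marker -> (intercept, slope per stage, noise SD); signs follow the
#: direction each marker moves with worsening fibrosis.
DEFAULT_SEROLOGY_EFFECTS = {
    "ast": (40.0, 15.0, 12.0),
    "alt": (45.0, 8.0, 12.0),
    "inr": (1.0, 0.08, 0.08),
    "albumin": (4.3, -0.15, 0.3),
    "sodium": (140.0, -1.2, 2.5),
    "platelets": (250.0, -25.0, 40.0),
    "creatinine": (0.8, 0.05, 0.15),
    "meld": (8.0, 2.0, 2.0),
    "fib4": (1.0, 0.8, 0.6),
}


def simulate_clinical(
    true_stages: np.ndarray,
    baseline_hazard: float = 0.0004,
    log_hr_per_stage: float = 0.693,
    censor_rate: float = 0.6,
    serology_effects: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Clinical records with stage-dependent hazard and serology.

    Event times are exponential with hazard ``baseline * exp(log_hr * stage)``
    (days); censoring is an independent exponential calibrated so the expected
    censored fraction matches ``censor_rate``.  Serology markers are linear in
    true stage plus Gaussian noise with the effect sizes in
    :data:`DEFAULT_SEROLOGY_EFFECTS`; sodium straddles the 137 cap so the
    capping rule is exercised.
    """
    if not np.isfinite(log_hr_per_stage):
        raise ValueError("log hazard ratio must be finite")
    if baseline_hazard <= 0 or not 0.0 <= censor_rate < 1.0:
        raise ValueError("baseline_hazard must be > 0 and censor_rate in [0, 1)")
    stages = np.asarray(true_stages, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(stages)
    hazards = baseline_hazard * np.exp(log_hr_per_stage * stages)
    event_times = rng.exponential(1.0 / hazards)
    if censor_rate > 0:
        def cens_frac(log_mu):
            mu = np.exp(log_mu)
            return float(np.mean(mu / (mu + hazards))) - censor_rate
        log_mu = brentq(cens_frac, np.log(hazards.min()) - 15, np.log(hazards.max()) + 15)
        censor_times = rng.exponential(np.exp(-log_mu), size=n)
    else:
        censor_times = np.full(n, np.inf)
    time = np.minimum(event_times, censor_times)
    event = event_times <= censor_times

    effects = serology_effects or DEFAULT_SEROLOGY_EFFECTS
    df = pd.DataFrame({
        "case_id": [f"C{i:04d}" for i in range(n)],
        "age": np.clip(rng.normal(53, 12, n), 18, 85),
        "sex": rng.choice(["F", "M"], size=n),
        "bmi": np.clip(rng.normal(34, 6, n), 18, 60),
        "true_stage": stages,
        "event": event,
        "time": time,
    })
    for marker, (icept, slope, sd) in effects.items():
        df[marker] = icept + slope * stages + rng.normal(0, sd, n)
    if "platelets" in df:
        df["platelets"] = df["platelets"].clip(lower=20)
    return df


# ---------------------------------------------------------------------------
# null/alternative Turing raters
# ---------------------------------------------------------------------------

def simulate_turing_rater(
    discriminability: float,
    n: int,
    seed: int = 0,
    rater_id: str = "sim",
    patch_size: int = 512,
) -> list[TuringResponse]:
    """Simulated rater guessing truth with probability ``0.5 + d/2``.

    ``d=0`` is the exact null (coin flips); ``d=1`` always matches the truth.
    ``n`` responses are returned, half real and half virtual.
    """
    if not 0.0 <= discriminability <= 1.0:
        raise ValueError("discriminability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    truths = np.array(["real", "virtual"])[np.arange(n) % 2]
    correct = rng.uniform(size=n) < 0.5 + discriminability / 2.0
    flip = {"real": "virtual", "virtual": "real"}
    return [TuringResponse(rater_id, patch_size, t, t if ok else flip[t])
            for t, ok in zip(truths, correct)]
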