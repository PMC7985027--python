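"""Real-vs-virtual patch sampling and per-rater Fisher exact realism tests.

A Turing test presents a rater with a blinded, shuffled mix of real and
virtual patches at a fixed size; the rater labels each as real or virtual and
the truth-by-guess contingency table is tested with Fisher's exact test.  The
test *passes* (supports realism) when it fails to reject the null of no
association at the chosen level — the rater cannot beat chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .tiling import SlideImage, white_fraction, DEFAULT_MAX_WHITE, DEFAULT_WHITE_THRESHOLD

logger = logging.getLogger(__name__)

DEFAULT_SIZES = (256, 512, 1024)
DEFAULT_N_PER_CLASS = 100

_REL_TOL = 1e-7


@dataclass
class TuringResponse:
    """One rater's call on one patch."""

    rater_id: str
    patch_size: int
    truth: str
    guess: str

    def __post_init__(self) -> None:
        if self.truth not in ("real", "virtual") or self.guess not in ("real", "virtual"):
            raise ValueError("truth and guess must be 'real' or 'virtual'")


def fisher_exact_2x2(table: np.ndarray) -> dict[str, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    The p-value sums hypergeometric probabilities (margins fixed) of all
    tables whose probability does not exceed the observed one, with a small
    relative tolerance on the comparison to absorb floating-point ties.  The
    odds ratio is the sample odds ratio ``ad/bc`` (``inf`` when only ``bc``
    has a zero, ``nan`` for 0/0).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.rint(t)):
            raise ValueError("table entries must be integers")
        t = np.rint(t).astype(np.int64)
    if (t < 0).any():
        raise ValueError("table entries must be nonnegative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n == 0:
        raise ValueError("table must have at least one nonzero margin")
    r1, c1 = a + b, a + c
    dist = hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - (c + d)), min(r1, c1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + _REL_TOL)].sum())
    p = min(1.0, p)
    if b * c == 0:
        odds = np.nan if a * d == 0 else np.inf
    else:
        odds = a * d / (b * c)
    return {"p_two_sided": p, "odds_ratio": float(odds)}


def sample_turing_patches(
    real_slides: Sequence[SlideImage],
    virtual_slides: Sequence[SlideImage],
    n_per_class: int = DEFAULT_N_PER_CLASS,
    sizes: Sequence[int] = DEFAULT_SIZES,
    rng_seed: int = 0,
    max_white: float = DEFAULT_MAX_WHITE,
    brightness_threshold: int = DEFAULT_WHITE_THRESHOLD,
    max_attempts_factor: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a blinded patch manifest for the realism study.

    For each size, up to ``n_per_class`` qualifying (low-whitespace) patches
    are drawn uniformly from each arm and shuffled into a presentation order.
    Returns ``(presentation, key)``: the presentation table carries no truth
    labels; unblinding requires joining the key on ``patch_id``.  If an arm
    cannot supply the requested count the achieved n is recorded with a
    warning.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    for size in sizes:
        for truth, slides in (("real", real_slides), ("virtual", virtual_slides)):
            usable = [s for s in slides if min(s.shape) >= size]
            if not usable:
                logger.warning("no slide large enough for %d-px patches in %s arm", size, truth)
                continue
            drawn = 0
            attempts = 0
            limit = max_attempts_factor * n_per_class
            while drawn < n_per_class and attempts < limit:
                attempts += 1
                s = usable[int(rng.integers(len(usable)))]
                h, w = s.shape
                r = int(rng.integers(0, h - size + 1))
                c = int(rng.integers(0, w - size + 1))
                patch = s.pixels[r:r + size, c:c + size]
                if white_fraction(patch, brightness_threshold) <= max_white:
                    rows.append({"size": size, "truth": truth, "slide_id": s.slide_id,
                                 "row": r, "col": c})
                    drawn += 1
            if drawn < n_per_class:
                logger.warning("only %d/%d qualifying %s patches at size %d",
                               drawn, n_per_class, truth, size)
    manifest = pd.DataFrame(rows, columns=["size", "truth", "slide_id", "row", "col"])
    order = rng.permutation(len(manifest))
    manifest = manifest.iloc[order].reset_index(drop=True)
    manifest.insert(0, "patch_id", [f"P{i:05d}" for i in range(len(manifest))])
    manifest["order"] = np.arange(len(manifest))
    key = manifest[["patch_id", "truth"]].copy()
    presentation = manifest.drop(columns=["truth"])
    return presentation, key


def responses_to_table(responses: Sequence[TuringResponse]) -> pd.DataFrame:
    return pd.DataFrame([{"rater_id": r.rater_id, "patch_size": r.patch_size,
                          "truth": r.truth, "guess": r.guess} for r in responses])


def run_turing_suite(
    responses: Sequence[TuringResponse] | pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (rater, size) Fisher test of truth vs guess.

    A cell passes when ``p >= alpha`` (the rater could not separate real from
    virtual).  Returns one row per nonempty cell with the 2x2 counts, p,
    odds ratio, and pass flag; cells with no responses are omitted.
    """
    df = responses if isinstance(responses, pd.DataFrame) else responses_to_table(responses)
    if df.empty:
        raise ValueError("no responses provided")
    out = []
    for (rater, size), cell in df.groupby(["rater_id", "patch_size"], sort=True):
        tab = np.zeros((2, 2), dtype=np.int64)
        for i, truth in enumerate(("real", "virtual")):
            for j, guess in enumerate(("real", "virtual")):
                tab[i, j] = int(((cell["truth"] == truth) & (cell["guess"] == guess)).sum())
        res = fisher_exact_2x2(tab)
        out.append({"rater_id": rater, "patch_size": size,
                    "n_real_real": tab[0, 0], "n_real_virtual": tab[0, 1],
                    "n_virtual_real": tab[1, 0], "n_virtual_virtual": tab[1, 1],
                    "p_two_sided": res["p_two_sided"], "odds_ratio": res["odds_ratio"],
                    "passed": res["p_two_sided"] >= alpha})
    results = pd.DataFrame(out)
    results.attrs["n_passed"] = int(results["passed"].sum())
    results.attrs["n_tests"] = len(results)
    return results
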