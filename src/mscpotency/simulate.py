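"""Seeded generators for every pipeline stage, with ground truth attached.

Each generator mirrors the statistical structure its downstream estimator
assumes: per-condition Gaussian NPX means with planted category effect
structure; longitudinal mouse severity trajectories with a multiplicative
treatment effect mapped onto the four clinical rubrics; barcode-channel
positive/background intensity mixtures with doublets; and CFSE generation
ladders with log-halving peaks.  All randomness flows through a single
``numpy.random.default_rng(seed)`` per call, so identical seeds reproduce
identical datasets bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cfse import LOG10_2
from .cytof import BarcodeScheme
from .npx import CONDITIONS, NPXMatrix

# ---------------------------------------------------------------------------
# NPX panel
# ---------------------------------------------------------------------------

#: Study design: replicate supernatants per condition.
DEFAULT_N_PER_CONDITION = {"Medium": 2, "PBMC": 3, "rMSC": 4,
                           "Coculture": 4, "D3cMSC": 4}

#: Planted category mix mirroring the reference study's 177-of-609 split.
DEFAULT_CATEGORY_FRACTIONS = {
    "consumed": 7 / 609, "constitutive": 65 / 609, "conditioning": 22 / 609,
    "inhibited": 10 / 609, "immunomodulatory": 40 / 609,
}


def _category_offsets(category: str, rng: np.random.Generator,
                      margin_scale: float) -> dict[str, float]:
    """Condition-mean offsets for one planted protein (log2 NPX units)."""
    m = rng.uniform(1.0, 2.5) * margin_scale
    z = {c: 0.0 for c in ("med", "pbmc", "rmsc", "coc", "d3")}
    if category == "consumed":
        z["med"] = m
        z["pbmc"] = m + rng.uniform(-0.2, 0.2) * margin_scale
    elif category == "conditioning":
        z["coc"] = m
        z["pbmc"] = rng.uniform(0.5, 1.5) * margin_scale
    elif category == "inhibited":
        z["d3"] = -m
    elif category == "immunomodulatory":
        z["d3"] = m
        z["coc"] = m - rng.uniform(0.0, 0.2) * margin_scale
    elif category == "constitutive":
        # Jitter kept below half the inhibited threshold so "near-equal"
        # can never fire a depression rule in the noiseless limit.
        for key in ("rmsc", "coc", "d3"):
            z[key] = m + rng.uniform(-0.08, 0.08) * margin_scale
    elif category != "null":
        raise ValueError(f"unknown category {category!r}")
    return z


def simulate_npx_panel(n_proteins: int = 609,
                       category_fractions: dict[str, float] | None = None,
                       margin_scale: float = 1.0, sigma: float = 0.15,
                       n_per_condition: dict[str, int] | None = None,
                       seed: int = 0) -> tuple[NPXMatrix, pd.DataFrame]:
    """Simulate a PEA panel with planted category effect structure.

    Returns ``(matrix, truth)`` where truth has columns ``protein, category``
    (``"null"`` for proteins with no planted effect).  ``margin_scale`` scales
    every planted offset; at 0 the panel is a pure null.
    """
    fractions = dict(DEFAULT_CATEGORY_FRACTIONS if category_fractions is None
                     else category_fractions)
    if sum(fractions.values()) > 1 + 1e-9 or any(v < 0 for v in fractions.values()):
        raise ValueError("category fractions must be >= 0 and sum to <= 1")
    n_cond = dict(DEFAULT_N_PER_CONDITION if n_per_condition is None
                  else n_per_condition)
    rng = np.random.default_rng(seed)

    categories: list[str] = []
    for cat, frac in fractions.items():
        categories.extend([cat] * int(round(frac * n_proteins)))
    categories.extend(["null"] * (n_proteins - len(categories)))
    categories = categories[:n_proteins]
    rng.shuffle(categories)

    samples, design = [], {}
    for cond in CONDITIONS:
        for i in range(n_cond.get(cond, 0)):
            sid = f"{cond}_{i + 1}"
            samples.append(sid)
            design[sid] = cond
    cond_keys = {"Medium": "med", "PBMC": "pbmc", "rMSC": "rmsc",
                 "Coculture": "coc", "D3cMSC": "d3"}

    values = np.empty((n_proteins, len(samples)))
    proteins = [f"P{i + 1:04d}" for i in range(n_proteins)]
    for i, cat in enumerate(categories):
        baseline = rng.uniform(1.0, 8.0)
        offsets = _category_offsets(cat, rng, margin_scale)
        col = 0
        for cond in CONDITIONS:
            mean = baseline + offsets[cond_keys[cond]]
            for _ in range(n_cond.get(cond, 0)):
                values[i, col] = mean + rng.normal(0.0, sigma)
                col += 1

    matrix = NPXMatrix(values=pd.DataFrame(values, index=proteins,
                                           columns=samples),
                       design=pd.Series(design))
    truth = pd.DataFrame({"protein": proteins, "category": categories})
    return matrix, truth


# ---------------------------------------------------------------------------
# Mouse cohort
# ---------------------------------------------------------------------------

#: Weekly disease severity of an untreated (placebo) animal, weeks 0..6.
#: Dimensionless; 0 = healthy, 1 ~ maximal rubric severity.
DEFAULT_SEVERITY_CURVE = (0.0, 0.1, 0.3, 0.45, 0.6, 0.75, 0.9)

DEFAULT_EFFECT_MULTIPLIER = {"placebo": 1.0, "rMSC": 0.9, "cMSC": 0.5}


@dataclass
class CohortTruth:
    effect_multiplier: dict[str, float]
    severity_curve: tuple[float, ...]
    deaths: list[str] = field(default_factory=list)
    humanization_failures: list[str] = field(default_factory=list)
    severity: pd.DataFrame | None = None


def _severity_to_measures(s: float, rng: np.random.Generator,
                          noise_sd: float,
                          base_weight: float, base_grip: float) -> dict:
    """Map latent severity to the four raw clinical measures.

    Each test observes severity with independent Gaussian noise; the maps are
    linear with saturation at the rubric extremes, scaled so that the expected
    GCS is approximately proportional to severity over [0, 1.2].
    """
    grades = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 3.0])
    s_w = s + rng.normal(0.0, noise_sd)
    s_g = s + rng.normal(0.0, noise_sd)
    s_t = s + rng.normal(0.0, noise_sd)
    s_b = s + rng.normal(0.0, noise_sd)
    weight = base_weight * (1.0 - 0.20 * s_w)           # loss% = 20 * s
    grip = base_grip * (1.0 - (0.40 * s_g - 0.04))      # loss% = 40 * s - 4
    grid_time = float(np.clip(66.0 - 60.0 * s_t, 0.0, 60.0))
    behavior = float(grades[np.argmin(np.abs(grades - np.clip(3.0 * s_b, 0, 3)))])
    return {"weight": float(weight), "grip": float(grip),
            "grid_time": grid_time, "behavior": behavior}


def simulate_cohort(n_per_arm: int = 9,
                    weeks: tuple[int, ...] = tuple(range(7)),
                    placebo_severity_curve: tuple[float, ...] | None = None,
                    effect_multiplier: dict[str, float] | None = None,
                    noise_sd: float = 0.08,
                    death_hazard: float = 0.0,
                    humanization_fail_rate: float = 0.0,
                    planted_failures: dict[str, int] | None = None,
                    baseline_week: int = 2,
                    base_weight: float = 25.0, base_grip: float = 150.0,
                    seed: int = 0) -> tuple[pd.DataFrame, CohortTruth]:
    """Simulate a longitudinal treated cohort with a multiplicative effect.

    Treatment is administered at ``baseline_week``; for later weeks the arm's
    severity is ``multiplier * curve(week)``, so on the baseline-normalized GCS
    scale the arm-vs-placebo ratio recovers the planted multiplier.  Deaths are
    Bernoulli per week with probability ``death_hazard * severity`` after the
    baseline week.  Humanization failures (human CD45+ < 0.4% at sacrifice) are
    planted either at a per-animal rate or exactly via ``planted_failures``
    (arm -> count).
    """
    curve = tuple(DEFAULT_SEVERITY_CURVE if placebo_severity_curve is None
                  else placebo_severity_curve)
    if any(c < 0 for c in curve):
        raise ValueError("severity curve must be non-negative")
    multipliers = dict(DEFAULT_EFFECT_MULTIPLIER if effect_multiplier is None
                       else effect_multiplier)
    rng = np.random.default_rng(seed)

    rows, sev_rows = [], []
    truth = CohortTruth(effect_multiplier=multipliers, severity_curve=curve)
    for arm, mult in multipliers.items():
        n_fail = (planted_failures or {}).get(arm, 0)
        for j in range(n_per_arm):
            animal = f"{arm}_{j + 1:02d}"
            fails = j < n_fail or rng.random() < humanization_fail_rate
            cd45 = (rng.uniform(0.05, 0.35) if fails
                    else rng.uniform(0.8, 25.0))
            if fails:
                truth.humanization_failures.append(animal)
            alive = True
            last = None
            for w in weeks:
                s = curve[w] if w <= baseline_week else mult * curve[w]
                sev_rows.append({"animal": animal, "arm": arm, "week": w,
                                 "severity": s})
                if alive and w > baseline_week and death_hazard > 0:
                    if rng.random() < min(1.0, death_hazard * s):
                        alive = False
                        truth.deaths.append(animal)
                if alive:
                    meas = _severity_to_measures(s, rng, noise_sd,
                                                 base_weight, base_grip)
                    last = meas
                else:
                    meas = last or _severity_to_measures(s, rng, noise_sd,
                                                         base_weight, base_grip)
                rows.append({"animal": animal, "arm": arm, "week": w,
                             **meas, "alive": alive, "cd45_pct": cd45})
    cohort = pd.DataFrame(rows)
    truth.severity = pd.DataFrame(sev_rows)
    return cohort, truth


# ---------------------------------------------------------------------------
# Barcoded mass-cytometry events
# ---------------------------------------------------------------------------

def simulate_barcoded_events(scheme: BarcodeScheme, n_per_sample: int = 500,
                             mu_pos: float = 6.0, sigma_pos: float = 0.8,
                             mu_bg: float = 1.0, sigma_bg: float = 0.8,
                             doublet_rate: float = 0.05,
                             seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate singlet and doublet events on the transformed intensity scale.

    Singlets: code channels ~ Normal(mu_pos, sigma_pos), all other scheme
    channels ~ Normal(mu_bg, sigma_bg).  Doublets (an extra ``doublet_rate``
    fraction of the singlet count) are channel-wise maxima of two random
    singlets and carry the truth label ``DOUBLET``.
    """
    if mu_pos <= mu_bg:
        raise ValueError("mu_pos must exceed mu_bg")
    rng = np.random.default_rng(seed)
    channels = scheme.channels
    samples = list(scheme.codes)

    def draw_singlet(sample: str) -> np.ndarray:
        code = scheme.codes[sample]
        return np.array([
            rng.normal(mu_pos, sigma_pos) if c in code
            else rng.normal(mu_bg, sigma_bg) for c in channels])

    events, labels = [], []
    for sample in samples:
        for _ in range(n_per_sample):
            events.append(draw_singlet(sample))
            labels.append(sample)
    n_doublets = int(round(doublet_rate * len(events)))
    for _ in range(n_doublets):
        a = draw_singlet(samples[rng.integers(len(samples))])
        b = draw_singlet(samples[rng.integers(len(samples))])
        events.append(np.maximum(a, b))
        labels.append("DOUBLET")

    table = pd.DataFrame(np.array(events), columns=channels)
    table.index = [f"e{i}" for i in range(len(table))]
    truth = pd.Series(labels, index=table.index, name="truth_sample")
    return table, truth


# ---------------------------------------------------------------------------
# CFSE
# ---------------------------------------------------------------------------

def simulate_cfse(n_events: int = 10_000, division_classes: int = 5,
                  undivided_mean: float = 4.0, class_spacing: float = LOG10_2,
                  peak_sigma: float = 0.05, divided_fraction: float = 0.6,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """One CFSE sample: a generation ladder with log-halving peaks.

    A ``divided_fraction`` of events is spread uniformly over generations
    1..``division_classes``; the rest sit in the undivided peak.  Returns
    ``(log10 intensities, generation per event)``.
    """
    if division_classes < 0:
        raise ValueError("division_classes must be >= 0")
    rng = np.random.default_rng(seed)
    if division_classes == 0:
        generations = np.zeros(n_events, dtype=int)
    else:
        divided = rng.random(n_events) < divided_fraction
        generations = np.where(
            divided, rng.integers(1, division_classes + 1, size=n_events), 0)
    intensities = rng.normal(undivided_mean - generations * class_spacing,
                             peak_sigma)
    return intensities, generations


DEFAULT_PLANTED_INHIBITION = {"rMSC": 0.30, "gMSC": 0.35, "D3-cMSC": 0.70}


def simulate_cfse_experiment(n_events: int = 10_000, division_classes: int = 5,
                             undivided_mean: float = 4.0,
                             class_spacing: float = LOG10_2,
                             peak_sigma: float = 0.05,
                             activated_fraction: float = 0.6,
                             planted_inhibition: dict[str, float] | None = None,
                             seed: int = 0) -> tuple[dict[str, np.ndarray], dict]:
    """Matched non-activated / activated / treated CFSE samples.

    Treated arms divide at ``activated_fraction * (1 - inhibition)``; the
    planted ordering (D3-cMSC most inhibitory) mirrors a supernatant
    comparison experiment.  Returns ``(samples, truth)``.
    """
    inhibition = dict(DEFAULT_PLANTED_INHIBITION if planted_inhibition is None
                      else planted_inhibition)
    rng = np.random.default_rng(seed)
    samples: dict[str, np.ndarray] = {}

    def one(fraction: float, classes: int) -> np.ndarray:
        sub_seed = int(rng.integers(2**31 - 1))
        x, _ = simulate_cfse(n_events=n_events, division_classes=classes,
                             undivided_mean=undivided_mean,
                             class_spacing=class_spacing,
                             peak_sigma=peak_sigma,
                             divided_fraction=fraction, seed=sub_seed)
        return x

    samples["non_activated"] = one(0.0, 0)
    samples["activated"] = one(activated_fraction, division_classes)
    for arm, inh in inhibition.items():
        samples[arm] = one(activated_fraction * (1.0 - inh), division_classes)
    truth = {"activated_fraction": activated_fraction,
             "planted_inhibition": inhibition,
             "division_classes": division_classes}
    return samples, truth
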