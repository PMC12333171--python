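"""Six-way rule-based categorization of differentially secreted proteins.

Each protein is summarised by its mean NPX in the five supernatant conditions
(Medium, PBMC, rMSC, Coculture, D3-cMSC) and assigned to one or more of six
categories by margin rules on condition differences (log2 NPX units):

* ``consumed`` -- high in cell-free medium, depleted by every MSC-containing
  condition (growth factors taken up by the adherent cells).  Terminal: a
  consumed protein carries no other label.
* ``conditioning`` -- enriched in the MSC+PBMC coculture over every other
  condition, with PBMC above medium (candidate conditioning agents).
* ``inhibited`` -- depressed in the D3-cMSC supernatant relative to both rMSC
  and coculture (shut down after conditioning).
* ``immunomodulatory`` -- maximal in D3-cMSC with at most a bounded deficit
  versus coculture (candidate effectors of the conditioned secretome).
* ``constitutive`` -- jointly and near-equally elevated in all MSC-containing
  conditions; evaluated only when none of the three labels above fired.
* ``unclassified`` -- no rule fired.

``conditioning``, ``inhibited`` and ``immunomodulatory`` may co-occur
(multi-label); the thresholds are exposed in :class:`ClassifierConfig` and on the
:class:`SecretomeClassifier` estimator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .npx import ConditionProfile

CATEGORIES = ("consumed", "constitutive", "conditioning", "inhibited",
              "immunomodulatory", "unclassified")

_ABS_TOL = 1e-9


@dataclass(frozen=True)
class ClassifierConfig:
    """Margin thresholds for the six category rules, in log2 NPX units.

    Defaults are the largest round margins below the smallest margin observed in
    the printed reference table for each rule (e.g. the weakest consumed protein
    clears 0.46, the weakest conditioning one 0.34, the weakest inhibited one
    0.24, the weakest immunomodulatory one 0.29; the largest tolerated D3-vs-
    coculture deficit among immunomodulatory proteins is 0.10).
    """

    tau_consumed: float = 0.4
    tau_conditioning: float = 0.3
    tau_inhibited: float = 0.2
    tau_immuno: float = 0.25
    delta_coc: float = 0.25
    tau_constitutive: float = 0.4
    eps_equal: float = 0.75

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")


@dataclass
class CategoryAssignment:
    """Per-protein label set plus the achieved margin of every evaluated rule."""

    protein: str
    labels: frozenset[str]
    margins: dict[str, float]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("labels must be nonempty; use {'unclassified'}")
        if "consumed" in self.labels and len(self.labels) > 1:
            raise ValueError("consumed is exclusive of all other labels")
        if "unclassified" in self.labels and len(self.labels) > 1:
            raise ValueError("unclassified is exclusive of all other labels")


@dataclass
class CategoryReport:
    """Per-category membership lists, counts and multi-label overlaps."""

    members: dict[str, list[str]]
    assignments: list[CategoryAssignment]

    @property
    def counts(self) -> dict[str, int]:
        return {cat: len(self.members[cat]) for cat in CATEGORIES}

    @property
    def overlaps(self) -> list[tuple[str, frozenset[str]]]:
        return [(a.protein, a.labels) for a in self.assignments
                if len(a.labels) > 1]

    @property
    def total_classified(self) -> int:
        return sum(1 for a in self.assignments
                   if a.labels != frozenset({"unclassified"}))


def _rule_margins(p: dict[str, float], cfg: ClassifierConfig) -> dict[str, float]:
    """Achieved margin of each rule; a rule fires when margin >= 0 (within tol).

    The margin is the amount by which the binding constraint clears its
    threshold, so raising a tau lowers the margin monotonically.
    """
    med, pbmc, rmsc, coc, d3 = (p["med"], p["pbmc"], p["rmsc"], p["coc"], p["d3"])
    msc_max, msc_min = max(rmsc, coc, d3), min(rmsc, coc, d3)
    return {
        "consumed": min(med - rmsc, med - coc, med - d3) - cfg.tau_consumed,
        "conditioning": min(
            # strict PBMC > Medium encoded as a positive margin requirement
            pbmc - med if pbmc - med > _ABS_TOL else -np.inf,
            min(coc - med, coc - rmsc, coc - d3) - cfg.tau_conditioning),
        "inhibited": min(rmsc - d3, coc - d3) - cfg.tau_inhibited,
        "immunomodulatory": min(
            d3 - max(med, pbmc, rmsc) - cfg.tau_immuno,
            (d3 - coc) + cfg.delta_coc),
        "constitutive": min(
            msc_min - max(med, pbmc) - cfg.tau_constitutive,
            cfg.eps_equal - (msc_max - msc_min)),
    }


def classify_protein(profile: ConditionProfile,
                     config: ClassifierConfig | None = None) -> CategoryAssignment:
    """Assign category labels to one condition profile.

    Precedence: ``consumed`` is terminal; ``conditioning``, ``inhibited`` and
    ``immunomodulatory`` may co-occur; ``constitutive`` is evaluated only when
    none of those fired; ``unclassified`` when nothing fired.
    """
    cfg = config or ClassifierConfig()
    vals = profile.as_dict()
    if not profile.classifiable:
        missing = [k for k, v in vals.items() if not np.isfinite(v)]
        return CategoryAssignment(profile.protein, frozenset({"unclassified"}),
                                  {"missing-condition": float("nan"),
                                   **{k: float("nan") for k in missing}})
    for key, value in vals.items():
        if not np.isfinite(value):
            raise ValueError(f"non-finite mean for {profile.protein}/{key}")

    margins = _rule_margins(vals, cfg)
    if margins["consumed"] >= -_ABS_TOL:
        return CategoryAssignment(profile.protein, frozenset({"consumed"}), margins)
    labels = {lab for lab in ("conditioning", "inhibited", "immunomodulatory")
              if margins[lab] >= -_ABS_TOL}
    if not labels and margins["constitutive"] >= -_ABS_TOL:
        labels = {"constitutive"}
    if not labels:
        labels = {"unclassified"}
    return CategoryAssignment(profile.protein, frozenset(labels), margins)


def classify_all(profiles: list[ConditionProfile],
                 config: ClassifierConfig | None = None) -> CategoryReport:
    """Classify every profile and compile the category report."""
    assignments = [classify_protein(p, config) for p in profiles]
    members = {cat: [a.protein for a in assignments if cat in a.labels]
               for cat in CATEGORIES}
    return CategoryReport(members=members, assignments=assignments)


def _agreement(profiles: list[ConditionProfile],
               truth: list[frozenset[str]],
               cfg: ClassifierConfig) -> float:
    """Fraction of profiles whose assigned label set equals the intended one."""
    hits = 0
    for profile, want in zip(profiles, truth):
        got = classify_protein(profile, cfg).labels
        hits += got == frozenset(want)
    return hits / len(profiles)


def calibrate_thresholds(profiles: list[ConditionProfile],
                         truth: list[frozenset[str] | set[str]],
                         grid: dict[str, list[float]]) -> tuple[ClassifierConfig, float]:
    """Grid-search thresholds maximising exact label-set agreement.

    ``grid`` maps :class:`ClassifierConfig` field names to candidate values;
    fields absent from the grid stay at their defaults.  Ties are broken toward
    larger (more conservative) thresholds.  Returns (best config, agreement).
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must map threshold names to nonempty value lists")
    if len(profiles) != len(truth):
        raise ValueError("profiles and truth must have equal length")
    truth = [frozenset(t) for t in truth]
    names = sorted(grid)
    best: tuple[float, tuple[float, ...], ClassifierConfig] | None = None
    for combo in itertools.product(*(sorted(grid[n]) for n in names)):
        cfg = replace(ClassifierConfig(), **dict(zip(names, combo)))
        score = _agreement(profiles, truth, cfg)
        key = (score, combo)  # ties -> larger thresholds win
        if best is None or key > (best[0], best[1]):
            best = (score, combo, cfg)
    return best[2], best[0]


def _profiles_from_frame(X) -> list[ConditionProfile]:
    cols = ["med", "pbmc", "rmsc", "coc", "d3"]
    if isinstance(X, pd.DataFrame):
        frame = X
        names = (frame["protein"].astype(str).tolist() if "protein" in frame
                 else [str(i) for i in frame.index])
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 5:
            raise ValueError("array input must be n x 5 (med, pbmc, rmsc, coc, d3)")
        frame = pd.DataFrame(arr, columns=cols)
        names = [str(i) for i in range(len(frame))]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"missing condition-mean columns: {missing}")
    return [ConditionProfile(protein=name, **{c: float(row[c]) for c in cols})
            for name, (_, row) in zip(names, frame.iterrows())]


class SecretomeClassifier(BaseEstimator):
    """Rule-based multilabel secretome classifier in the sklearn idiom.

    Parameters are the seven margin thresholds of :class:`ClassifierConfig`.
    ``fit`` is optional: without ``y`` it only validates the input and freezes
    the configured thresholds; with ``y`` (iterables of intended labels) and a
    ``grid``, it grid-calibrates the thresholds by exact-agreement.

    Attributes
    ----------
    config_ : ClassifierConfig
        Thresholds in effect after ``fit``.
    agreement_score_ : float
        Exact-membership agreement achieved during calibration (1.0 when no
        calibration was requested).
    """

    def __init__(self, tau_consumed: float = 0.4, tau_conditioning: float = 0.3,
                 tau_inhibited: float = 0.2, tau_immuno: float = 0.25,
                 delta_coc: float = 0.25, tau_constitutive: float = 0.4,
                 eps_equal: float = 0.75,
                 grid: dict[str, list[float]] | None = None):
        self.tau_consumed = tau_consumed
        self.tau_conditioning = tau_conditioning
        self.tau_inhibited = tau_inhibited
        self.tau_immuno = tau_immuno
        self.delta_coc = delta_coc
        self.tau_constitutive = tau_constitutive
        self.eps_equal = eps_equal
        self.grid = grid

    def _config(self) -> ClassifierConfig:
        return ClassifierConfig(
            tau_consumed=self.tau_consumed,
            tau_conditioning=self.tau_conditioning,
            tau_inhibited=self.tau_inhibited,
            tau_immuno=self.tau_immuno,
            delta_coc=self.delta_coc,
            tau_constitutive=self.tau_constitutive,
            eps_equal=self.eps_equal)

    def fit(self, X, y=None):
        profiles = _profiles_from_frame(X)
        if y is not None and self.grid is not None:
            self.config_, self.agreement_score_ = calibrate_thresholds(
                profiles, [frozenset(t) for t in y], self.grid)
        else:
            self.config_ = self._config()
            self.agreement_score_ = 1.0
        self.categories_ = list(CATEGORIES)
        return self

    def _effective_config(self) -> ClassifierConfig:
        return getattr(self, "config_", None) or self._config()

    def assign(self, X) -> list[CategoryAssignment]:
        """Full per-protein assignments (labels + rule margins)."""
        cfg = self._effective_config()
        return [classify_protein(p, cfg) for p in _profiles_from_frame(X)]

    def predict(self, X) -> pd.DataFrame:
        """Multilabel indicator frame, one row per protein, one column per category."""
        assignments = self.assign(X)
        return pd.DataFrame(
            [[cat in a.labels for cat in CATEGORIES] for a in assignments],
            columns=list(CATEGORIES),
            index=[a.protein for a in assignments]).astype(int)

    def report(self, X) -> CategoryReport:
        cfg = self._effective_config()
        return classify_all(_profiles_from_frame(X), cfg)

    def score(self, X, y) -> float:
        """Exact label-set agreement against intended labels ``y``."""
        return _agreement(_profiles_from_frame(X), [frozenset(t) for t in y],
                          self._effective_config())
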