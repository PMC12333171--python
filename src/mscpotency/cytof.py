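"""Combinatorial surface-barcode design and debarcoding for mass cytometry.

Samples are multiplexed by staining one surface antigen (CD90 on MSC) with a
unique k-subset of m metal-isotope-tagged antibody clones; pooled events are
demultiplexed computationally.  With k = 3 positives per code, m = 6 channels
suffice for 15 samples per tube (C(6,3) = 20 codes).

Two debarcoding methods are provided.  ``rank`` sorts the scheme channels per
event and takes the top-k set as the candidate code, requiring the intensity
gap between the k-th and (k+1)-th ranked channels (the separation) to clear a
minimum -- the standard doublet guard.  ``threshold`` is plain Boolean gating:
the positive set (channels above per-channel cutoffs) must equal a code
exactly.  Intensities are consumed on a transformed scale (arcsinh, cofactor 5
by convention); transforming raw counts is the simulator's concern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

UNASSIGNED = "UNASSIGNED"


@dataclass
class BarcodeScheme:
    """k-of-m code book: sample id -> k-subset of isotope channels."""

    channels: list[str]
    k: int
    codes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        seen: dict[frozenset[str], str] = {}
        for sample, code in self.codes.items():
            code = frozenset(code)
            self.codes[sample] = code
            if len(code) != self.k:
                raise ValueError(f"code for {sample} has {len(code)} channels, "
                                 f"expected k={self.k}")
            if not code <= set(self.channels):
                raise ValueError(f"code for {sample} uses unknown channels")
            if code in seen:
                raise ValueError(f"codes for {sample} and {seen[code]} collide")
            seen[code] = sample
        self.code_to_sample = seen

    def to_json(self, path) -> None:
        payload = {"channels": self.channels, "k": self.k,
                   "codes": {s: sorted(c) for s, c in self.codes.items()}}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "BarcodeScheme":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(channels=payload["channels"], k=payload["k"],
                   codes={s: frozenset(c) for s, c in payload["codes"].items()})


def design_scheme(m: int, k: int = 3, n_samples: int = 15,
                  channels: list[str] | None = None,
                  sample_ids: list[str] | None = None) -> BarcodeScheme:
    """Assign the first ``n_samples`` k-subsets (lexicographic) to samples.

    Deterministic: the same (m, k, n) always yields the same code book.
    """
    capacity = comb(m, k)
    if n_samples > capacity:
        raise ValueError(
            f"cannot encode {n_samples} samples with C({m},{k})={capacity} codes")
    if channels is None:
        channels = [f"ch{i + 1}" for i in range(m)]
    if len(channels) != m:
        raise ValueError("channels list must have length m")
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    if len(sample_ids) != n_samples:
        raise ValueError("sample_ids list must have length n_samples")
    subsets = combinations(range(m), k)
    codes = {sid: frozenset(channels[i] for i in subset)
             for sid, subset in zip(sample_ids, subsets)}
    return BarcodeScheme(channels=list(channels), k=k, codes=codes)


@dataclass
class DebarcodeResult:
    """Per-event assignment plus the k/(k+1) separation gap."""

    assignments: pd.Series      # event -> sample id or UNASSIGNED
    separation: pd.Series       # intensity gap, >= 0
    method: str

    @property
    def yield_fraction(self) -> float:
        return float((self.assignments != UNASSIGNED).mean())


class Debarcoder(BaseEstimator):
    """Sample-assignment estimator over barcode-channel event intensities.

    Parameters
    ----------
    scheme : BarcodeScheme
        The k-of-m code book.
    method : {"rank", "threshold"}
        ``rank``: top-k channel set must be a code and the k/(k+1) gap must be
        at least ``min_separation``.  ``threshold``: the above-cutoff channel
        set must equal a code exactly.
    min_separation : float
        Minimum k/(k+1) intensity gap for the rank method (transformed units).
    channel_cutoffs : dict
        Per-channel positivity cutoffs, required by the threshold method.
    """

    def __init__(self, scheme: BarcodeScheme | None = None, method: str = "rank",
                 min_separation: float = 1.0,
                 channel_cutoffs: dict[str, float] | None = None):
        self.scheme = scheme
        self.method = method
        self.min_separation = min_separation
        self.channel_cutoffs = channel_cutoffs

    def _validate(self, events: pd.DataFrame) -> pd.DataFrame:
        if self.scheme is None:
            raise ValueError("a BarcodeScheme is required")
        if self.method not in ("rank", "threshold"):
            raise ValueError(f"unknown method {self.method!r}")
        missing = [c for c in self.scheme.channels if c not in events.columns]
        if missing:
            raise ValueError(f"events table lacks scheme channels: {missing}")
        if self.method == "rank" and self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.method == "threshold":
            if self.channel_cutoffs is None or any(
                    c not in self.channel_cutoffs for c in self.scheme.channels):
                raise ValueError("threshold method needs a cutoff per scheme channel")
        block = events[self.scheme.channels]
        if not np.isfinite(block.to_numpy(dtype=float)).all():
            raise ValueError("non-finite intensities in scheme channels")
        return block.astype(float)

    def fit(self, events: pd.DataFrame, y=None):
        block = self._validate(events)
        self.channels_ = list(self.scheme.channels)
        self.codes_ = dict(self.scheme.codes)
        self.n_features_in_ = block.shape[1]
        return self

    def predict(self, events: pd.DataFrame) -> pd.Series:
        return self.debarcode(events).assignments

    def debarcode(self, events: pd.DataFrame) -> DebarcodeResult:
        block = self._validate(events)
        intensities = block.to_numpy()
        k = self.scheme.k
        channels = np.array(self.scheme.channels)
        code_map = self.scheme.code_to_sample

        # Sort descending; ties broken by channel order (stable sort on -x).
        order = np.argsort(-intensities, axis=1, kind="stable")
        sorted_int = np.take_along_axis(intensities, order, axis=1)
        if k < len(channels):
            separation = sorted_int[:, k - 1] - sorted_int[:, k]
        else:
            separation = sorted_int[:, k - 1] - np.min(intensities, axis=1)
            separation = np.maximum(separation, 0.0)

        assigned = []
        if self.method == "rank":
            for i in range(len(intensities)):
                top = frozenset(channels[order[i, :k]])
                sample = code_map.get(top)
                # A tie across the k/(k+1) boundary means the top-k set is
                # ambiguous: separation 0 is never assignable (when k < m).
                ambiguous = k < len(channels) and separation[i] <= 0
                if (sample is not None and not ambiguous
                        and separation[i] >= self.min_separation):
                    assigned.append(sample)
                else:
                    assigned.append(UNASSIGNED)
        else:
            cutoffs = np.array([self.channel_cutoffs[c]
                                for c in self.scheme.channels])
            positive = intensities > cutoffs
            for i in range(len(intensities)):
                pos = frozenset(channels[positive[i]])
                assigned.append(code_map.get(pos, UNASSIGNED))

        index = block.index
        return DebarcodeResult(
            assignments=pd.Series(assigned, index=index, name="sample"),
            separation=pd.Series(separation, index=index, name="separation"),
            method=self.method)


def debarcode(events: pd.DataFrame, scheme: BarcodeScheme, method: str = "rank",
              min_separation: float = 1.0,
              channel_cutoffs: dict[str, float] | None = None) -> DebarcodeResult:
    """Functional wrapper over :class:`Debarcoder`."""
    return Debarcoder(scheme=scheme, method=method,
                      min_separation=min_separation,
                      channel_cutoffs=channel_cutoffs).debarcode(events)


@dataclass
class DebarcodeMetrics:
    yield_fraction: float
    accuracy: float               # NaN when nothing was assigned
    confusion: pd.DataFrame       # truth x assigned counts
    note: str = ""


def debarcode_metrics(result: DebarcodeResult,
                      truth: pd.Series) -> DebarcodeMetrics:
    """Yield, accuracy of assigned events, and the per-sample confusion matrix.

    ``truth`` labels doublets as ``DOUBLET``; they count against yield but a
    doublet can never be "correct".
    """
    if len(truth) != len(result.assignments):
        raise ValueError("truth and assignments length mismatch")
    truth = pd.Series(truth.to_numpy(), index=result.assignments.index)
    assigned_mask = result.assignments != UNASSIGNED
    n_assigned = int(assigned_mask.sum())
    if n_assigned == 0:
        accuracy, note = float("nan"), "no events assigned; accuracy undefined"
    else:
        correct = (result.assignments[assigned_mask]
                   == truth[assigned_mask]).sum()
        accuracy, note = float(correct / n_assigned), ""
    confusion = pd.crosstab(truth, result.assignments, dropna=False)
    return DebarcodeMetrics(yield_fraction=result.yield_fraction,
                            accuracy=accuracy, confusion=confusion, note=note)
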