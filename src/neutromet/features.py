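"""From corrected spectra to an analysis-ready feature matrix.

Bin integration (trapezoidal area over each pattern interval, with the
intensity interpolated at the exact bin boundaries so adjacent sub-bins
tile exactly), total-area normalisation, Pareto scaling, and
correlation-reliability-score (CRS) selection of one representative bin
per annotated metabolite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import pandas as pd

from .exceptions import InvariantError
from .io import FeatureTable, PatternFile, Spectrum

logger = logging.getLogger("neutromet")


# --------------------------------------------------------------------------
# integration
# --------------------------------------------------------------------------


def _bin_area(s: Spectrum, left: float, right: float) -> float:
    """Trapezoidal integral of intensity over [right, left] ppm.

    Endpoints are linearly interpolated onto the exact bin boundaries, so
    splitting a bin at any interior point and summing the pieces
    reproduces the whole-bin area exactly.
    """
    lo, hi = right, left
    inner = (s.ppm > lo) & (s.ppm < hi)
    x = np.concatenate(([lo], s.ppm[inner], [hi]))
    y = np.concatenate(
        (
            [np.interp(lo, s.ppm, s.intensity)],
            s.intensity[inner],
            [np.interp(hi, s.ppm, s.intensity)],
        )
    )
    return float(np.trapezoid(y, x))


def integrate_bins(spectra, pattern: PatternFile) -> FeatureTable:
    """Integrate every pattern bin in every spectrum.

    ``spectra`` is a :class:`~neutromet.synthetic.SpectrumSet` or a plain
    sequence of :class:`Spectrum`. Negative integrals (baseline
    undershoot in low-SNR spectra) are floored at 0 with a logged
    warning; a bin lying entirely outside a spectrum's axis is an error.
    """
    if hasattr(spectra, "spectra"):
        spec_list = list(spectra.spectra)
        sample_meta = spectra.design.copy()
    else:
        spec_list = list(spectra)
        sample_meta = pd.DataFrame(
            {
                "sample_id": [
                    s.meta.get("sample_id", f"sample_{i}")
                    for i, s in enumerate(spec_list)
                ]
            }
        )
        for key in ("group", "cell_count", "n_scans"):
            if any(key in s.meta for s in spec_list):
                sample_meta[key] = [s.meta.get(key, "") for s in spec_list]
    if not spec_list:
        raise InvariantError("no spectra to integrate")
    bins = list(pattern.bins)
    values = np.empty((len(spec_list), len(bins)))
    n_floored = 0
    for i, s in enumerate(spec_list):
        for j, b in enumerate(bins):
            if b.right_ppm >= s.ppm[-1] or b.left_ppm <= s.ppm[0]:
                sid = s.meta.get("sample_id", f"sample_{i}")
                raise InvariantError(
                    f"bin {b.bin_id!r} [{b.right_ppm}, {b.left_ppm}] lies outside "
                    f"the axis of sample {sid!r}"
                )
            area = _bin_area(s, b.left_ppm, b.right_ppm)
            if area < 0:
                n_floored += 1
                area = 0.0
            values[i, j] = area
    if n_floored:
        logger.warning(
            "floored %d negative bin integrals at 0 (baseline undershoot)", n_floored
        )
    return FeatureTable(values, sample_meta, bins, state="raw")


# --------------------------------------------------------------------------
# normalisation and scaling
# --------------------------------------------------------------------------


def ta_normalise(t: FeatureTable) -> FeatureTable:
    """Total-area normalisation: divide each sample's row by its sum."""
    if t.state != "raw":
        raise InvariantError(f"ta_normalise expects state='raw', got {t.state!r}")
    sums = t.values.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        sid = (
            t.sample_meta.iloc[bad[0]].get("sample_id", f"row {bad[0]}")
            if "sample_id" in t.sample_meta.columns
            else f"row {bad[0]}"
        )
        raise InvariantError(f"zero total area for sample {sid!r}")
    return FeatureTable(
        t.values / sums[:, None], t.sample_meta.copy(), list(t.bins), "normalised"
    )


def pareto_fit(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Column means and Pareto divisors sqrt(sample SD); zero-variance
    columns get divisor 1 (they become all-zero after centering)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    divisor = np.where(sd > 0, np.sqrt(sd), 1.0)
    return mean, divisor


def pareto_apply(X: np.ndarray, mean: np.ndarray, divisor: np.ndarray) -> np.ndarray:
    return (X - mean) / divisor


def pareto_scale(t: FeatureTable) -> FeatureTable:
    """Pareto scaling: centre each column, divide by sqrt(column SD).

    A compromise between unit-variance and no scaling: large peaks keep
    more weight than under autoscaling while low-intensity bins are still
    lifted. Requires a normalised table with >= 2 samples.
    """
    if t.state != "normalised":
        raise InvariantError(f"pareto_scale expects state='normalised', got {t.state!r}")
    if t.n_samples < 2:
        raise InvariantError("Pareto scaling needs at least 2 samples")
    mean, divisor = pareto_fit(t.values)
    return FeatureTable(
        pareto_apply(t.values, mean, divisor), t.sample_meta.copy(), list(t.bins), "scaled"
    )


# --------------------------------------------------------------------------
# CRS filtering
# --------------------------------------------------------------------------


@dataclass
class CRSMetabolite:
    metabolite_id: str
    candidates: list
    scores: dict
    chosen: str
    tie_broken: bool


@dataclass
class CRSResult:
    """Outcome of representative-bin selection.

    Per annotated metabolite: the candidate bin ids, each candidate's CRS
    (mean Pearson correlation with the metabolite's other candidate bins
    across samples; defined as 1 for a single candidate), the chosen bin,
    and whether a tie-break was needed. ``removed_unknown_bins`` lists the
    discarded unannotated bins; ``removed_candidate_bins`` the annotated
    candidates that lost to a sibling.
    """

    metabolites: list = field(default_factory=list)
    removed_unknown_bins: list = field(default_factory=list)
    removed_candidate_bins: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.metabolites:
            for cand in m.candidates:
                rows.append(
                    {
                        "metabolite_id": m.metabolite_id,
                        "bin_id": cand,
                        "crs_score": m.scores[cand],
                        "chosen": cand == m.chosen,
                        "tie_broken": m.tie_broken,
                    }
                )
        return pd.DataFrame(rows)


def crs_select(t: FeatureTable, pattern: PatternFile) -> Tuple[FeatureTable, CRSResult]:
    """Keep one representative bin per annotated metabolite; drop unknowns.

    The correlation reliability score of a candidate bin is its mean
    Pearson correlation (across samples, whole cohort) with the other
    candidate bins of the same metabolite. The representative is the
    argmax; exact ties break by larger median intensity in the supplied
    table, then lexicographic bin_id, and are flagged. Correlations are
    computed on the TA-normalised table, before any scaling.
    """
    if t.state != "normalised":
        raise InvariantError(f"crs_select expects state='normalised', got {t.state!r}")
    col = {b: i for i, b in enumerate(t.bin_ids)}
    groups: dict = {}
    unknown: list = []
    for b in t.bins:
        if b.is_unknown:
            unknown.append(b.bin_id)
        else:
            groups.setdefault(b.group_key, []).append(b.bin_id)

    metabolites: list = []
    removed_candidates: list = []
    chosen_ids: list = []
    for met_id, cand in groups.items():
        if len(cand) == 1:
            scores = {cand[0]: 1.0}
            chosen, tie = cand[0], False
        else:
            X = t.values[:, [col[c] for c in cand]]
            sds = X.std(axis=0, ddof=0)
            if np.all(sds == 0):
                raise InvariantError(
                    f"metabolite {met_id!r}: all candidate bins have zero variance"
                )
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(X, rowvar=False)
            scores = {}
            for i, c in enumerate(cand):
                others = np.delete(corr[i], i)
                scores[c] = float(np.nanmean(others)) if np.isfinite(others).any() else float("-inf")
            best = max(scores.values())
            tied = [c for c in cand if abs(scores[c] - best) <= 1e-12]
            tie = len(tied) > 1
            if tie:
                medians = {c: float(np.median(t.values[:, col[c]])) for c in tied}
                top = max(medians.values())
                tied = sorted([c for c in tied if medians[c] == top])
            chosen = tied[0]
        metabolites.append(
            CRSMetabolite(
                metabolite_id=met_id,
                candidates=list(cand),
                scores=scores,
                chosen=chosen,
                tie_broken=tie,
            )
        )
        removed_candidates.extend(c for c in cand if c != chosen)
        chosen_ids.append(chosen)

    # preserve spectral (pattern) order of the representative bins
    order = {b: i for i, b in enumerate(t.bin_ids)}
    chosen_ids.sort(key=lambda b: order[b])
    filtered = t.select_bins(chosen_ids)
    result = CRSResult(
        metabolites=metabolites,
        removed_unknown_bins=unknown,
        removed_candidate_bins=removed_candidates,
    )
    return filtered, result
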