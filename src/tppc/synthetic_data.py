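"""Synthetic matched transcript/metabolite datasets with planted couplings.

The generator emulates the shape of real integrated datasets: many
transcripts riding on a low-rank latent covariance (a handful of regulatory
"programs"), far fewer metabolites, and modest sample counts. Metabolite
pairs are planted in one of two ways:

* **TPC pairs** share a linear combination of the *transcript* latent
  factors, so their association is mediated by transcriptional variance and
  should vanish once the leading transcript PCs are partialled out;
* **PPC pairs** share a fresh latent vector independent of the transcript
  factors, so their association survives the partialling.

All remaining metabolites are independent noise. Planted pairs use disjoint
metabolite sets so ground-truth labels are unambiguous. Gaussian noise
throughout; measurement-error models, batch effects and autocorrelation are
deliberately not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import SpecificationError
from .io_data import Layer, MatchedDataset, OmicsMatrix

__all__ = ["SyntheticSpec", "GroundTruth", "generate_dataset", "evaluate_recovery"]


@dataclass(frozen=True)
class SyntheticSpec:
    """World description for :func:`generate_dataset`.

    Defaults are the benchmark scenario used throughout the test suite:
    60 samples, 300 transcripts on 3 latent factors, 40 metabolites of which
    8 + 8 disjoint pairs are planted with coupling 0.85 over noise sd 0.4.
    """

    n_samples: int = 60
    n_transcripts: int = 300
    n_metabolites: int = 40
    n_factors: int = 3
    n_tpc_pairs: int = 8
    n_ppc_pairs: int = 8
    loading_scale: float = 1.0
    coupling_strength: float = 0.85
    noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_transcripts, self.n_metabolites, self.n_factors) < 1:
            raise SpecificationError("all dimensions must be >= 1")
        if min(self.n_tpc_pairs, self.n_ppc_pairs) < 0:
            raise SpecificationError("planted pair counts must be >= 0")
        if 2 * (self.n_tpc_pairs + self.n_ppc_pairs) > self.n_metabolites:
            raise SpecificationError(
                "planted pairs need disjoint metabolites: "
                f"2*({self.n_tpc_pairs}+{self.n_ppc_pairs}) > {self.n_metabolites}"
            )
        if self.n_factors >= self.n_samples:
            raise SpecificationError(
                f"n_factors ({self.n_factors}) must be < n_samples ({self.n_samples})"
            )
        if not 0 < self.coupling_strength <= 1:
            raise SpecificationError(
                f"coupling_strength must be in (0, 1], got {self.coupling_strength}"
            )
        if self.noise_sd <= 0:
            raise SpecificationError(f"noise_sd must be positive, got {self.noise_sd}")


@dataclass(frozen=True)
class GroundTruth:
    """Planted labels: unordered metabolite pair -> 'TPC' or 'PPC'."""

    labels: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for (a, b), label in self.labels.items():
            if a >= b:
                raise SpecificationError(f"pair ({a!r}, {b!r}) not lexicographically ordered")
            if label not in ("TPC", "PPC"):
                raise SpecificationError(f"unknown label {label!r}")
            if a in seen or b in seen:
                offender = a if a in seen else b
                raise SpecificationError(
                    f"metabolite {offender!r} appears in more than one planted pair"
                )
            seen.update((a, b))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metabolite_1": a, "metabolite_2": b, "label": lab}
            for (a, b), lab in sorted(self.labels.items())
        ]
        return pd.DataFrame(rows, columns=["metabolite_1", "metabolite_2", "label"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GroundTruth":
        return cls(
            {
                (str(r.metabolite_1), str(r.metabolite_2)): str(r.label)
                for r in frame.itertuples(index=False)
            }
        )


def generate_dataset(spec: SyntheticSpec) -> tuple[MatchedDataset, GroundTruth]:
    """Draw one matched dataset with planted pair couplings.

    Transcripts are ``loadings @ F + noise`` with ``F`` an
    ``(n_factors x n_samples)`` standard-normal latent matrix. Each planted
    pair's two metabolites share ``coupling_strength * s`` plus independent
    noise, where ``s`` is a unit-variance shared signal: a normalised linear
    combination of rows of ``F`` for TPC pairs, or a fresh standard-normal
    vector for PPC pairs. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, q = spec.n_samples, spec.n_factors
    F = rng.standard_normal((q, n))
    loadings = rng.standard_normal((spec.n_transcripts, q)) * spec.loading_scale
    transcripts = loadings @ F + rng.standard_normal((spec.n_transcripts, n)) * spec.noise_sd

    metabolites = rng.standard_normal((spec.n_metabolites, n)) * spec.noise_sd
    met_ids = [f"m{k:03d}" for k in range(spec.n_metabolites)]
    labels: dict[tuple[str, str], str] = {}
    row = 0
    for _ in range(spec.n_tpc_pairs):
        w = rng.standard_normal(q)
        w /= np.linalg.norm(w)
        shared = w @ F  # unit population variance: w is a unit vector
        for offset in (0, 1):
            metabolites[row + offset] = (
                spec.coupling_strength * shared
                + rng.standard_normal(n) * spec.noise_sd
            )
        labels[tuple(sorted((met_ids[row], met_ids[row + 1])))] = "TPC"
        row += 2
    for _ in range(spec.n_ppc_pairs):
        shared = rng.standard_normal(n)
        for offset in (0, 1):
            metabolites[row + offset] = (
                spec.coupling_strength * shared
                + rng.standard_normal(n) * spec.noise_sd
            )
        labels[tuple(sorted((met_ids[row], met_ids[row + 1])))] = "PPC"
        row += 2

    sample_ids = tuple(f"s{k:03d}" for k in range(n))
    dataset = MatchedDataset(
        transcripts=OmicsMatrix(
            transcripts,
            tuple(f"t{k:04d}" for k in range(spec.n_transcripts)),
            sample_ids,
            Layer.TRANSCRIPT,
        ),
        metabolites=OmicsMatrix(
            metabolites, tuple(met_ids), sample_ids, Layer.METABOLITE
        ),
    )
    return dataset, GroundTruth(labels)


def evaluate_recovery(predicted, truth: GroundTruth) -> pd.DataFrame:
    """Recall/precision per planted label plus false discoveries elsewhere.

    ``predicted`` is a list of categorized :class:`PairStatistics`. Undefined
    ratios (no predictions of a label) are NaN, not 0. The returned frame has
    one row per label and one ``unplanted`` row with the count and fraction
    of unplanted pairs assigned to either category.
    """
    pred = {
        tuple(sorted((s.metabolite_1, s.metabolite_2))): s.category
        for s in predicted
        if s.category in ("TPC", "PPC")
    }
    rows = []
    for label in ("TPC", "PPC"):
        truth_pairs = {p for p, lab in truth.labels.items() if lab == label}
        pred_pairs = {p for p, lab in pred.items() if lab == label}
        n_true, n_pred = len(truth_pairs), len(pred_pairs)
        hits = len(truth_pairs & pred_pairs)
        other = "PPC" if label == "TPC" else "TPC"
        crossed = sum(1 for p in truth_pairs if pred.get(p) == other)
        rows.append(
            {
                "label": label,
                "n_planted": n_true,
                "n_predicted": n_pred,
                "recall": hits / n_true if n_true else np.nan,
                "precision": hits / n_pred if n_pred else np.nan,
                "cross_assignment_rate": crossed / n_true if n_true else np.nan,
            }
        )
    all_pairs = {
        tuple(sorted((s.metabolite_1, s.metabolite_2))) for s in predicted
    }
    unplanted = all_pairs - set(truth.labels)
    false_pos = sum(1 for p in unplanted if p in pred)
    rows.append(
        {
            "label": "unplanted",
            "n_planted": len(unplanted),
            "n_predicted": false_pos,
            "recall": np.nan,
            "precision": np.nan,
            "cross_assignment_rate": np.nan,
        }
    )
    frame = pd.DataFrame(rows)
    frame["false_discovery_fraction"] = np.nan
    if len(unplanted):
        frame.loc[frame["label"] == "unplanted", "false_discovery_fraction"] = (
            false_pos / len(unplanted)
        )
    return frame
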