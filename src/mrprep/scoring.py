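"""Score and rank candidate search models.

Two headline numbers guide model choice.  The mean pLDDT of a hit, where 70
or more indicates a high-confidence prediction, banded on the conventional
0-100 colour scale (< 50 very low, 50-70 low, 70-90 confident, >= 90 very
high).  And a coverage-weighted score — mean pLDDT times the fraction of the
target sequence the hit covers — so that a mediocre full-length hit can
outrank an excellent fragment.  The coverage weighting follows the idea of
the H-score used in search-model ranking; the exact published formula is not
reproduced here and no numerical equality with it is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .confidence import ConfidenceProfile
from .model_io import PredictedModel
from .splitting import REMOVED, DomainPartition

__all__ = [
    "ModelScore",
    "average_plddt",
    "plddt_band",
    "coverage_weighted_score",
    "score_model",
    "domain_report",
]

BAND_EDGES = ((90.0, "very_high"), (70.0, "confident"), (50.0, "low"))


def plddt_band(mean_plddt: float) -> str:
    """Confidence band for a mean pLDDT on the 0-100 scale."""
    for edge, band in BAND_EDGES:
        if mean_plddt >= edge:
            return band
    return "very_low"


@dataclass
class ModelScore:
    """Summary scores for one candidate model against a target length."""

    mean_plddt: float          # 0-100
    coverage: float            # fraction of target length covered, (0, 1]
    coverage_weighted: float   # mean_plddt * coverage, 0-100
    band: str
    n_residues: int


def average_plddt(profile: ConfidenceProfile) -> tuple[float, str]:
    """Arithmetic mean pLDDT on the 0-100 scale, with its confidence band."""
    values = profile.plddt100()
    mean = float(np.mean(values))
    return mean, plddt_band(mean)


def coverage_weighted_score(profile: ConfidenceProfile, target_length: int) -> float:
    """Sum of per-residue pLDDT divided by the target length (0-100 scale).

    Equal to mean pLDDT times coverage: monotone in both confidence and the
    fraction of the target the hit covers.
    """
    values = profile.plddt100()
    if target_length < len(values):
        raise ValueError(
            f"hit exceeds target length: {len(values)} residues vs {target_length}"
        )
    if target_length < 1:
        raise ValueError("target length must be >= 1")
    return float(np.sum(values)) / target_length


def score_model(profile: ConfidenceProfile, target_length: int | None = None) -> ModelScore:
    """Full score record; ``target_length`` defaults to the profile length."""
    n = len(profile)
    target_length = n if target_length is None else target_length
    mean, band = average_plddt(profile)
    weighted = coverage_weighted_score(profile, target_length)
    return ModelScore(
        mean_plddt=mean,
        coverage=n / target_length,
        coverage_weighted=weighted,
        band=band,
        n_residues=n,
    )


def _sequence_ranges(model: PredictedModel, indices: list[int]) -> str:
    residues = list(model.residues())
    parts: list[str] = []
    start = prev = None
    prev_chain = None
    for i in indices:
        res = residues[i]
        if (
            prev is not None
            and res.chain_id == prev_chain
            and res.seq_id == prev + 1
        ):
            prev = res.seq_id
            parts[-1] = f"{prev_chain}:{start}-{prev}"
        else:
            start = prev = res.seq_id
            prev_chain = res.chain_id
            parts.append(f"{prev_chain}:{start}-{prev}")
    return ",".join(parts)


def radius_of_gyration(coords: np.ndarray) -> float:
    """Unweighted radius of gyration of a point set (Angstrom)."""
    centroid = coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((coords - centroid) ** 2, axis=1))))


def domain_report(
    model: PredictedModel,
    partition: DomainPartition,
    profile: ConfidenceProfile,
) -> pd.DataFrame:
    """Per-domain summary table: size, ranges, mean score, Rg, centroid.

    One row per domain plus a ``removed`` row summarising residues outside
    the partition.  The score column is mean pLDDT on the 0-100 scale for
    pLDDT profiles and the raw mean otherwise.
    """
    if len(profile) != model.n_residues:
        raise ValueError(
            f"length mismatch: profile {len(profile)} vs model {model.n_residues}"
        )
    partition.validate(model.n_residues)
    try:
        values = np.asarray(profile.plddt100())
        score_name = "mean_plddt"
    except ValueError:
        values = np.asarray(profile.values)
        score_name = "mean_value"
    coords = model.representative_coordinates()

    rows = []
    for domain_id, domain in enumerate(partition.domains):
        sub = coords[domain]
        centroid = sub.mean(axis=0)
        rows.append(
            {
                "domain": domain_id,
                "size": len(domain),
                "ranges": _sequence_ranges(model, domain),
                score_name: float(values[domain].mean()),
                "radius_gyration": radius_of_gyration(sub),
                "centroid_x": float(centroid[0]),
                "centroid_y": float(centroid[1]),
                "centroid_z": float(centroid[2]),
            }
        )
    removed = [i for i, lab in enumerate(partition.labels) if lab == REMOVED]
    rows.append(
        {
            "domain": REMOVED,
            "size": len(removed),
            "ranges": _sequence_ranges(model, removed),
            score_name: float(values[removed].mean()) if removed else float("nan"),
            "radius_gyration": radius_of_gyration(coords[removed]) if removed else float("nan"),
            "centroid_x": float("nan"),
            "centroid_y": float("nan"),
            "centroid_z": float("nan"),
        }
    )
    return pd.DataFrame(rows)
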