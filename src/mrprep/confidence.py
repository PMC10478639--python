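"""Confidence-metric detection, B-factor conversion, pruning and cleanup.

Structure predictors store a per-residue confidence estimate in the B-factor
column of their output: AlphaFold-family programs write pLDDT (0-100, or 0-1
in some pipelines), RoseTTAFold writes an estimated r.m.s.d. from the true
structure in Angstrom.  Molecular-replacement programs expect real isotropic
B factors, which they use to down-weight uncertain atoms, so the confidence
must be converted before the model is used as a search model.

The conversion used here maps pLDDT (as a fraction p) to an error estimate

    rmsd(p) = min(cap, scale * exp(slope * (midpoint - p)))

with defaults scale = 1.5 A, slope = 4, midpoint = 0.7, cap = 20 A, and then
to an isotropic displacement parameter via B = (8 pi^2 / 3) * rmsd^2.  At the
midpoint pLDDT of 70 this gives rmsd = 1.5 A and B ~ 59.2 A^2.  All four
constants are exposed in :class:`ConversionParams`.

The module also removes residues below a pLDDT threshold (default 70 -- a
residue at exactly 70 is kept), drops short disconnected chain segments, and
trims a model to residue ranges matched to a target sequence.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .model_io import PredictedModel

__all__ = [
    "ConfidenceKind",
    "ConfidenceProfile",
    "ConversionParams",
    "detect_confidence_kind",
    "profile_from_model",
    "plddt_to_rmsd",
    "rmsd_to_bfactor",
    "bfactor_to_rmsd",
    "convert_to_bfactors",
    "prune_low_confidence",
    "remove_short_segments",
    "trim_to_target",
    "alignment_ranges",
]

B_PER_RMSD_SQ = 8.0 * math.pi**2 / 3.0


class ConfidenceKind(enum.Enum):
    """What the B column of a predicted model actually holds."""

    PLDDT100 = "plddt100"   # pLDDT on the 0-100 scale (AlphaFold default)
    PLDDT1 = "plddt1"       # pLDDT rescaled to 0-1
    RMSD_ANGSTROM = "rmsd_angstrom"  # estimated r.m.s.d., Angstrom (RoseTTAFold)
    BFACTOR_ALREADY = "bfactor_already"  # already a crystallographic B, A^2


@dataclass
class ConfidenceProfile:
    """Per-residue confidence values aligned to a model's residue order."""

    kind: ConfidenceKind
    values: list[float]

    def __post_init__(self) -> None:
        vals = [float(v) for v in self.values]
        if not vals:
            raise ValueError("no residues: empty confidence profile")
        if any(v < 0 for v in vals):
            raise ValueError("invalid confidence values: negative entry")
        if self.kind is ConfidenceKind.PLDDT100 and max(vals) > 100:
            raise ValueError("invalid confidence values: pLDDT above 100")
        if self.kind is ConfidenceKind.PLDDT1 and max(vals) > 1:
            raise ValueError("invalid confidence values: pLDDT fraction above 1")
        self.values = vals

    def __len__(self) -> int:
        return len(self.values)

    def plddt100(self) -> list[float]:
        """Values on the 0-100 pLDDT scale (only for pLDDT kinds)."""
        if self.kind is ConfidenceKind.PLDDT100:
            return list(self.values)
        if self.kind is ConfidenceKind.PLDDT1:
            return [v * 100.0 for v in self.values]
        raise ValueError(f"threshold kind mismatch: profile kind is {self.kind.value}")


@dataclass
class ConversionParams:
    """Constants of the pLDDT -> r.m.s.d. -> B conversion (see module docs)."""

    lddt_midpoint: float = 0.7   # pLDDT fraction at which rmsd equals lddt_scale
    lddt_scale: float = 1.5      # Angstrom
    lddt_slope: float = 4.0      # dimensionless
    rmsd_cap: float = 20.0       # Angstrom

    def __post_init__(self) -> None:
        if min(self.lddt_midpoint, self.lddt_scale, self.lddt_slope, self.rmsd_cap) <= 0:
            raise ValueError("conversion parameters must be positive")
        if self.rmsd_cap < self.lddt_scale:
            raise ValueError("rmsd_cap must be at least lddt_scale")


def detect_confidence_kind(
    values, declared: ConfidenceKind | None = None
) -> ConfidenceKind:
    """Classify what metric a list of B-column values holds.

    A declared kind always wins.  Otherwise: all values in [0, 1] is a
    pLDDT fraction; values in [0, 100] with at least 5% above 20 is 0-100
    pLDDT; values confined to [0, 20] are taken as r.m.s.d. estimates; and
    anything else is treated as an already-converted B factor.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("no residues: empty value list")
    if any(v < 0 for v in vals):
        raise ValueError("invalid confidence values: negative entry")
    if declared is not None:
        return declared
    hi = max(vals)
    if hi <= 1.0:
        return ConfidenceKind.PLDDT1
    frac_above_20 = sum(v > 20 for v in vals) / len(vals)
    if hi <= 100.0 and frac_above_20 >= 0.05:
        return ConfidenceKind.PLDDT100
    if hi <= 20.0:
        return ConfidenceKind.RMSD_ANGSTROM
    return ConfidenceKind.BFACTOR_ALREADY


def profile_from_model(
    model: PredictedModel, declared: ConfidenceKind | None = None
) -> ConfidenceProfile:
    """Build a confidence profile from a model's raw B-column values."""
    values = model.raw_confidences()
    kind = detect_confidence_kind(values, declared)
    return ConfidenceProfile(kind=kind, values=values)


# ---------------------------------------------------------------------------
# conversion closed forms


def plddt_to_rmsd(p: float, params: ConversionParams | None = None) -> float:
    """Estimated r.m.s.d. (Angstrom) for a pLDDT fraction p in [0, 1].

    Strictly decreasing in p below the cap; rmsd(midpoint) = scale exactly.
    """
    params = params or ConversionParams()
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"pLDDT out of range: {p}")
    return min(
        params.rmsd_cap,
        params.lddt_scale * math.exp(params.lddt_slope * (params.lddt_midpoint - p)),
    )


def rmsd_to_bfactor(r: float) -> float:
    """Isotropic B (A^2) for a coordinate error of r Angstrom: (8 pi^2/3) r^2."""
    if r < 0:
        raise ValueError(f"invalid rmsd: {r}")
    return B_PER_RMSD_SQ * r * r


def bfactor_to_rmsd(b: float) -> float:
    """Inverse of :func:`rmsd_to_bfactor`."""
    if b < 0:
        raise ValueError(f"invalid B factor: {b}")
    return math.sqrt(b / B_PER_RMSD_SQ)


def _profile_to_bfactors(profile: ConfidenceProfile, params: ConversionParams) -> list[float]:
    if profile.kind is ConfidenceKind.BFACTOR_ALREADY:
        return list(profile.values)
    if profile.kind is ConfidenceKind.RMSD_ANGSTROM:
        return [rmsd_to_bfactor(v) for v in profile.values]
    fractions = (
        profile.values
        if profile.kind is ConfidenceKind.PLDDT1
        else [v / 100.0 for v in profile.values]
    )
    return [rmsd_to_bfactor(plddt_to_rmsd(p, params)) for p in fractions]


def convert_to_bfactors(
    model: PredictedModel,
    profile: ConfidenceProfile | None = None,
    params: ConversionParams | None = None,
) -> PredictedModel:
    """Replace every atom's B-column value with the converted B factor.

    pLDDT profiles go through the rmsd closed form; r.m.s.d. profiles go
    straight to B = (8 pi^2/3) r^2; a profile that already holds B factors
    is returned unchanged.  When no profile is given one is detected from
    the model.  Returns a new model; the input is untouched.
    """
    profile = profile if profile is not None else profile_from_model(model)
    params = params or ConversionParams()
    if len(profile) != model.n_residues:
        raise ValueError(
            f"profile/model length mismatch: {len(profile)} != {model.n_residues}"
        )
    out = model.copy()
    if profile.kind is ConfidenceKind.BFACTOR_ALREADY:
        return out
    bfactors = _profile_to_bfactors(profile, params)
    for res, b in zip(out.residues(), bfactors):
        for atom in res.atoms:
            atom.b_value = b
    record = (
        f"bconv[{profile.kind.value}->B;mid={params.lddt_midpoint}"
        f";scale={params.lddt_scale};slope={params.lddt_slope};cap={params.rmsd_cap}]"
    )
    out.source_tag = (out.source_tag + " " + record).strip()
    return out


# ---------------------------------------------------------------------------
# pruning and cleanup


def prune_low_confidence(
    model: PredictedModel,
    profile: ConfidenceProfile | None = None,
    threshold: float = 70.0,
    rmsd_threshold: float | None = None,
) -> PredictedModel:
    """Remove residues whose confidence falls below the threshold.

    For pLDDT profiles the threshold is on the 0-100 scale (default 70) and a
    residue at exactly the threshold is kept.  An r.m.s.d. profile needs an
    explicit ``rmsd_threshold`` in Angstrom (residues with a larger estimated
    error are removed).  Order-preserving and idempotent.
    """
    profile = profile if profile is not None else profile_from_model(model)
    if len(profile) != model.n_residues:
        raise ValueError(
            f"profile/model length mismatch: {len(profile)} != {model.n_residues}"
        )
    if profile.kind is ConfidenceKind.RMSD_ANGSTROM:
        if rmsd_threshold is None:
            raise ValueError(
                "threshold kind mismatch: r.m.s.d. profile needs an explicit "
                "rmsd_threshold in Angstrom"
            )
        keep = [i for i, v in enumerate(profile.values) if v <= rmsd_threshold]
    elif profile.kind in (ConfidenceKind.PLDDT100, ConfidenceKind.PLDDT1):
        scaled = profile.plddt100()
        keep = [i for i, v in enumerate(scaled) if v >= threshold]
    else:
        raise ValueError(
            "threshold kind mismatch: cannot prune on an already-converted B column"
        )
    return model.subset(keep)


def chain_segments(
    model: PredictedModel, break_distance: float = 4.5
) -> list[list[int]]:
    """Contiguous segments of residue indices (file order).

    A segment continues while the chain id is unchanged, author numbering is
    consecutive, and successive representative-atom distances stay within
    ``break_distance`` (the virtual Calpha-Calpha bond is ~3.8 A).
    """
    coords = model.representative_coordinates()
    segments: list[list[int]] = []
    current: list[int] = []
    prev = None
    for i, res in enumerate(model.residues()):
        if prev is not None:
            same_chain = res.chain_id == prev.chain_id
            consecutive = res.seq_id == prev.seq_id + 1 and not res.icode
            close = np.linalg.norm(coords[i] - coords[i - 1]) <= break_distance
            if not (same_chain and consecutive and close):
                segments.append(current)
                current = []
        current.append(i)
        prev = res
    if current:
        segments.append(current)
    return segments


def remove_short_segments(
    model: PredictedModel, min_len: int = 3, break_distance: float = 4.5
) -> PredictedModel:
    """Drop chain segments shorter than ``min_len`` residues.

    Pruning low-confidence residues leaves behind short disconnected
    fragments that contribute noise rather than signal in molecular
    replacement; this removes them.  An empty result is allowed.
    """
    keep: list[int] = []
    for segment in chain_segments(model, break_distance):
        if len(segment) >= min_len:
            keep.extend(segment)
    return model.subset(keep)


def trim_to_target(
    model: PredictedModel, keep: list[tuple[str, int, int]]
) -> PredictedModel:
    """Retain residues inside the union of inclusive (chain, start, end) ranges."""
    known_chains = set(model.chains)
    for chain_id, start, end in keep:
        if chain_id not in known_chains:
            raise ValueError(f"unknown chain: {chain_id!r}")
        if start > end:
            raise ValueError(f"malformed range: {chain_id}:{start}-{end}")
    indices = [
        i
        for i, res in enumerate(model.residues())
        if any(
            res.chain_id == c and s <= res.seq_id <= e for c, s, e in keep
        )
    ]
    return model.subset(indices)


def alignment_ranges(
    model: PredictedModel,
    target_sequence: str,
    chain_id: str | None = None,
) -> list[tuple[str, int, int]]:
    """Residue ranges of the model aligned to a target sequence.

    Globally aligns the model chain's one-letter sequence against the target
    (BLOSUM62, affine gaps) and returns the maximal runs of model residues
    that sit in aligned (non-gap) columns, ready for :func:`trim_to_target`.
    The scoring scheme is configuration, not contract.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices
    from Bio.SeqUtils import seq1

    if chain_id is None:
        chain_id = next(iter(model.chains))
    residues = model.chains[chain_id]
    model_seq = "".join(
        (seq1(r.res_name) or "X").upper() or "X" for r in residues
    ).replace(" ", "X")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    alignment = aligner.align(model_seq, target_sequence.upper())[0]

    aligned_model_idx: list[int] = []
    for (m_start, m_end), _ in zip(*alignment.aligned):
        aligned_model_idx.extend(range(m_start, m_end))

    ranges: list[tuple[str, int, int]] = []
    for idx in aligned_model_idx:
        seq_id = residues[idx].seq_id
        if ranges and seq_id == ranges[-1][2] + 1:
            ranges[-1] = (chain_id, ranges[-1][1], seq_id)
        else:
            ranges.append((chain_id, seq_id, seq_id))
    return ranges
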