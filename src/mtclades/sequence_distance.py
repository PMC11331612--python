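"""Aligned mtDNA sequences: FASTA I/O, poly-C masking, pairwise distances.

Human mtDNA alignments carry a few regions that are unreliable to align —
notably the poly-cytosine stretches at rCRS coordinates 303–315 and
16183–16194 — which are conventionally removed before distance computation.
:class:`MaskSpec` expresses such regions either in reference (rCRS)
coordinates, mapped through the non-gap positions of a designated reference
row, or directly as alignment columns.

Distances are raw mismatch proportions (p-distance) or mismatch counts under
pairwise deletion: any site where either sequence carries a gap or an
ambiguous base is excluded for that pair.  Downstream uses (ordination,
within-group spread) are rank-driven, so no multiple-hit correction is
applied here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import MaskError, UndefinedDistanceError

__all__ = [
    "Msa",
    "MaskSpec",
    "DEFAULT_MASK",
    "mask_positions",
    "pairwise_differences",
    "read_fasta_msa",
]

_VALID = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class Msa:
    """A multiple sequence alignment over {A, C, G, T, N, -}.

    Input is uppercased; ambiguity codes other than N are conservatively
    mapped to N (excluded pairwise rather than scored).  ``aln_coords`` and
    ``ref_coords`` carry each surviving column's 1-based coordinate in the
    *original* alignment and reference frames, so repeated masking with the
    same specification is a no-op after the first application.
    """

    ids: List[str]
    matrix: np.ndarray  # shape (n_samples, n_columns), dtype S1
    reference_id: Optional[str] = None
    aln_coords: Optional[np.ndarray] = None
    ref_coords: Optional[np.ndarray] = None  # 0 where the reference is gapped
    mask_history: Tuple["MaskSpec", ...] = ()

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise MaskError("duplicate sequence ids in alignment")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise MaskError("alignment matrix shape does not match ids")
        if self.reference_id is not None and self.reference_id not in self.ids:
            raise MaskError(f"reference id {self.reference_id!r} not in alignment")
        if self.aln_coords is None:
            self.aln_coords = np.arange(1, self.matrix.shape[1] + 1)

    @classmethod
    def from_strings(
        cls, records: Sequence[Tuple[str, str]], reference_id: Optional[str] = None
    ) -> "Msa":
        ids = [r[0] for r in records]
        seqs = [r[1].upper() for r in records]
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise MaskError(f"sequences have unequal lengths: {sorted(lengths)}")
        mat = np.array([np.frombuffer(s.encode(), dtype="S1") for s in seqs])
        # anything outside {A,C,G,T,-} becomes N
        known = np.isin(mat, np.frombuffer(b"ACGT-", dtype="S1"))
        mat = np.where(known, mat, np.array(b"N", dtype="S1"))
        return cls(ids=ids, matrix=mat, reference_id=reference_id)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, sample_id: str) -> str:
        row = self.matrix[self.ids.index(sample_id)]
        return row.tobytes().decode()

    def drop(self, sample_id: str) -> "Msa":
        """Alignment without one row (e.g. remove the reference before distances)."""
        keep = [i for i, s in enumerate(self.ids) if s != sample_id]
        ref = self.reference_id if self.reference_id != sample_id else None
        return Msa(
            ids=[self.ids[i] for i in keep], matrix=self.matrix[keep], reference_id=ref,
            aln_coords=self.aln_coords, ref_coords=self.ref_coords,
            mask_history=self.mask_history,
        )

    def to_fasta(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for sid, row in zip(self.ids, self.matrix):
                fh.write(f">{sid}\n{row.tobytes().decode()}\n")


def read_fasta_msa(path, reference_id: Optional[str] = None) -> Msa:
    """Read an aligned FASTA file (wrapped or single-line) into an :class:`Msa`."""
    from Bio import SeqIO

    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise MaskError(f"no sequences found in {path}")
    return Msa.from_strings(records, reference_id=reference_id)


@dataclass(frozen=True)
class MaskSpec:
    """1-based inclusive coordinate ranges to remove from an alignment.

    ``space="reference"`` counts coordinates over the non-gap characters of
    the designated reference row; ``space="alignment"`` addresses alignment
    columns directly.
    """

    ranges: Tuple[Tuple[int, int], ...] = ()
    space: str = "reference"

    def __post_init__(self) -> None:
        if self.space not in ("reference", "alignment"):
            raise MaskError(f"unknown mask space {self.space!r}")
        norm = []
        for lo, hi in self.ranges:
            if lo < 1 or hi < lo:
                raise MaskError(f"invalid 1-based range ({lo}, {hi})")
            norm.append((lo, hi))
        norm.sort()
        merged: List[List[int]] = []
        for lo, hi in norm:
            if merged and lo <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        object.__setattr__(self, "ranges", tuple((lo, hi) for lo, hi in merged))

    def covers(self, coord: int) -> bool:
        return any(lo <= coord <= hi for lo, hi in self.ranges)


#: The conventional mtDNA mask: both poly-C regions, in rCRS coordinates.
DEFAULT_MASK = MaskSpec(ranges=((303, 315), (16183, 16194)), space="reference")


def mask_positions(msa: Msa, spec: MaskSpec) -> Msa:
    """Delete masked columns from every row of the alignment.

    In reference space, a column is removed iff the reference row has a
    non-gap character there whose 1-based rank among the reference's non-gap
    characters falls in a masked range; columns where the reference is gapped
    are kept (they have no reference coordinate).  Coordinates always refer
    to the original, unmasked frames, so masking is idempotent.
    """
    if not spec.ranges:
        return msa
    fresh = not msa.mask_history
    if spec.space == "alignment":
        coords = msa.aln_coords
        if fresh and any(hi > msa.n_columns for _, hi in spec.ranges):
            raise MaskError(f"mask range exceeds alignment length {msa.n_columns}")
    else:
        if msa.ref_coords is not None:
            coords = msa.ref_coords
        else:
            if msa.reference_id is None:
                raise MaskError("reference-space masking requires a designated reference row")
            ref_row = msa.matrix[msa.ids.index(msa.reference_id)]
            non_gap = ref_row != b"-"
            coords = np.where(non_gap, np.cumsum(non_gap), 0)
        ref_len = int(coords.max()) if coords.size else 0
        if fresh and any(hi > ref_len for _, hi in spec.ranges):
            raise MaskError(f"mask range exceeds reference length {ref_len}: {spec.ranges}")
    in_mask = np.zeros(msa.n_columns, dtype=bool)
    for lo, hi in spec.ranges:
        in_mask |= (coords >= lo) & (coords <= hi)
    if in_mask.all():
        warnings.warn("mask removes every alignment column", stacklevel=2)
    keep = ~in_mask
    return Msa(
        ids=list(msa.ids),
        matrix=msa.matrix[:, keep],
        reference_id=msa.reference_id,
        aln_coords=msa.aln_coords[keep],
        ref_coords=(msa.ref_coords[keep] if msa.ref_coords is not None
                    else (coords[keep] if spec.space == "reference" else None)),
        mask_history=msa.mask_history + (spec,),
    )


def pairwise_differences(msa: Msa, mode: str = "p") -> pd.DataFrame:
    """Pairwise sequence distances under pairwise deletion.

    Parameters
    ----------
    msa : Msa
    mode : {"p", "count"}
        ``"p"`` returns the mismatch proportion over comparable sites;
        ``"count"`` returns the raw mismatch count.

    Raises
    ------
    UndefinedDistanceError
        If some pair shares no comparable site (each pair is named).
    """
    if mode not in ("p", "count"):
        raise UndefinedDistanceError(f"unknown distance mode {mode!r}")
    if not msa.ids:
        raise UndefinedDistanceError("alignment is empty")
    valid = np.isin(msa.matrix, _VALID)  # False at gaps and Ns
    n = len(msa.ids)
    out = np.zeros((n, n))
    for i in range(n):
        comp = valid[i] & valid[i + 1 :]
        diff = comp & (msa.matrix[i] != msa.matrix[i + 1 :])
        n_comp = comp.sum(axis=1)
        zero = np.nonzero(n_comp == 0)[0]
        if zero.size:
            j = int(zero[0]) + i + 1
            raise UndefinedDistanceError(
                f"no comparable sites between {msa.ids[i]!r} and {msa.ids[j]!r}"
            )
        n_diff = diff.sum(axis=1)
        vals = n_diff / n_comp if mode == "p" else n_diff.astype(float)
        out[i, i + 1 :] = vals
        out[i + 1 :, i] = vals
    return pd.DataFrame(out, index=msa.ids, columns=msa.ids)
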