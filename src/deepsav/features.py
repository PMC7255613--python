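"""Per-position 90-feature vectors and 21-residue windows for the classifier.

Feature layout of one position (fixed order, 90 values):

====== =============================================================
slice  content
====== =============================================================
0:20   wild-type amino-acid one-hot
20:40  mutant amino-acid one-hot (zero except at the window centre)
40:60  alignment profile frequencies
60     conservation score
61:70  3-state secondary structure x 3 predictors (H/E/C each)
70:73  disorder propensity x 3 predictors
73     low-complexity (seg) flag
74     coiled-coil (ncoils) flag
75:78  SIGNAL / TRANSIT / TRANSMEM flags
78:81  MOD_RES phosphorylation / acetylation / methylation flags
81:89  DISULFID CARBOHYD METAL BINDING ACT_SITE SITE LIPID MOTIF
89     zero-padding indicator (1 outside the protein, else 0)
====== =============================================================

Neighbouring positions of a window encode their own residue in the wild-type
block and zeros in the mutant block; only the centre position carries the
substitution.  Window slots beyond the protein ends are zero-filled with the
padding indicator set to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields
from typing import Mapping

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, N_AA

logger = logging.getLogger(__name__)

N_FEATURES = 90
WINDOW = 21
HALF_WIDTH = 10
WINDOW_SIZE = N_FEATURES * WINDOW  # 1890

#: The 28 annotation columns consumed from the per-position annotation table,
#: in the order they occupy feature slots 61..88.
ANNOTATION_COLUMNS = (
    "H_psipred", "E_psipred", "C_psipred",
    "H_spd3", "E_spd3", "C_spd3",
    "H_psspred", "E_psspred", "C_psspred",
    "disopred", "spotd", "iupred2a",
    "seg", "ncoils",
    "SIGNAL", "TRANSIT", "TRANSMEM",
    "P_MODRES", "A_MODRES", "M_MODRES",
    "DISULFID", "CARBOHYD", "METAL", "BINDING",
    "ACT_SITE", "SITE", "LIPID", "MOTIF",
)

# feature-group slices inside the 90-vector (padding slot 89 is never masked)
GROUP_SLICES: dict[str, slice] = {
    "aa": slice(0, 40),
    "profile": slice(40, 60),
    "conservation": slice(60, 61),
    "sec_struct": slice(61, 70),
    "disorder": slice(70, 73),
    "seg": slice(73, 74),
    "coiled_coil": slice(74, 75),
    "uniprot_feat": slice(75, 89),
}


class ReferenceMismatchError(ValueError):
    """Variant wild-type residue disagrees with the reference sequence."""


@dataclass
class FeatureMask:
    """Named switches over feature groups; disabled groups are zeroed.

    Mirrors the feature-combination experiments (AA-only, AA+consv, ALL-prof,
    ...): each attribute enables one group of the 90-vector.
    """

    aa: bool = True
    profile: bool = True
    conservation: bool = True
    sec_struct: bool = True
    disorder: bool = True
    seg: bool = True
    coiled_coil: bool = True
    uniprot_feat: bool = True

    @classmethod
    def all_features(cls) -> "FeatureMask":
        return cls()

    @classmethod
    def only(cls, *groups: str) -> "FeatureMask":
        """A mask enabling just the named groups (e.g. ``only('aa', 'conservation')``)."""
        valid = {f.name for f in dc_fields(cls)}
        unknown = set(groups) - valid
        if unknown:
            raise ValueError(f"unknown feature groups: {sorted(unknown)}")
        return cls(**{name: name in groups for name in valid})

    @classmethod
    def all_except(cls, *groups: str) -> "FeatureMask":
        valid = {f.name for f in dc_fields(cls)}
        unknown = set(groups) - valid
        if unknown:
            raise ValueError(f"unknown feature groups: {sorted(unknown)}")
        return cls(**{name: name not in groups for name in valid})

    def keep_vector(self) -> np.ndarray:
        """90-length 0/1 vector of retained feature slots (padding always kept)."""
        keep = np.ones(N_FEATURES)
        for name, sl in GROUP_SLICES.items():
            if not getattr(self, name):
                keep[sl] = 0.0
        return keep


class GeneData:
    """Per-gene inputs for encoding: sequence, profile, conservation, annotations.

    Annotations missing for the gene are imputed as zeros (with a logged
    warning), never an error.
    """

    def __init__(
        self,
        gene: str,
        sequence: str,
        profile: np.ndarray,
        conservation: np.ndarray,
        annotations: np.ndarray | pd.DataFrame | None = None,
    ) -> None:
        L = len(sequence)
        profile = np.asarray(profile, dtype=float)
        conservation = np.asarray(conservation, dtype=float)
        if profile.shape != (L, N_AA):
            raise ValueError(f"profile shape {profile.shape} != ({L}, {N_AA})")
        if conservation.shape != (L,):
            raise ValueError("conservation length mismatch")
        if annotations is None:
            logger.warning("gene %s has no annotations; imputing zeros", gene)
            ann = np.zeros((L, len(ANNOTATION_COLUMNS)))
        elif isinstance(annotations, pd.DataFrame):
            missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
            if missing:
                raise ValueError(f"annotation table missing columns: {missing}")
            ann = annotations.loc[:, list(ANNOTATION_COLUMNS)].to_numpy(dtype=float)
        else:
            ann = np.asarray(annotations, dtype=float)
        if ann.shape != (L, len(ANNOTATION_COLUMNS)):
            raise ValueError(f"annotations shape {ann.shape} != ({L}, {len(ANNOTATION_COLUMNS)})")
        self.gene = gene
        self.sequence = sequence
        self.profile = profile
        self.conservation = conservation
        self.annotations = ann
        self._base = None  # lazy (L, 90) per-position base matrix

    def __len__(self) -> int:
        return len(self.sequence)

    def base_matrix(self) -> np.ndarray:
        """(L, 90) matrix of per-position features with the mutant block zeroed."""
        if self._base is None:
            L = len(self.sequence)
            base = np.zeros((L, N_FEATURES))
            for i, aa in enumerate(self.sequence):
                idx = AA_INDEX.get(aa)
                if idx is not None:
                    base[i, idx] = 1.0
            base[:, 40:60] = self.profile
            base[:, 60] = self.conservation
            base[:, 61:89] = self.annotations
            self._base = base
        return self._base


def encode_position(gene_data: GeneData, position: int, wt: str, mut: str) -> np.ndarray:
    """The 90-feature vector of the variant's own (centre) position.

    ``position`` is 1-based on the ungapped reference sequence; ``wt`` must
    match the reference residue there.
    """
    _check_variant(gene_data, position, wt, mut)
    vec = gene_data.base_matrix()[position - 1].copy()
    vec[20 + AA_INDEX[mut]] = 1.0
    return vec


def encode_window(
    gene_data: GeneData, position: int, wt: str, mut: str, half_width: int = HALF_WIDTH
) -> np.ndarray:
    """(21, 90) feature window centred on the variant position.

    Slots before residue 1 or past the protein end are zero-filled with the
    padding indicator set to 1.
    """
    _check_variant(gene_data, position, wt, mut)
    L = len(gene_data)
    width = 2 * half_width + 1
    window = np.zeros((width, N_FEATURES))
    window[:, 89] = 1.0  # assume padded; real slots overwrite below
    lo = max(1, position - half_width)
    hi = min(L, position + half_width)
    rows = gene_data.base_matrix()[lo - 1 : hi]
    offset = lo - (position - half_width)
    window[offset : offset + (hi - lo + 1)] = rows
    window[half_width, 20 + AA_INDEX[mut]] = 1.0
    return window


def _check_variant(gene_data: GeneData, position: int, wt: str, mut: str) -> None:
    if not 1 <= position <= len(gene_data):
        raise ValueError(
            f"position {position} outside {gene_data.gene} (length {len(gene_data)})"
        )
    if wt not in AA_INDEX or mut not in AA_INDEX:
        raise ValueError(f"nonstandard amino acid in {wt}->{mut}")
    ref = gene_data.sequence[position - 1]
    if ref != wt:
        raise ReferenceMismatchError(
            f"{gene_data.gene} position {position}: reference is {ref!r}, variant says {wt!r}"
        )


def apply_mask(window: np.ndarray, mask: FeatureMask) -> np.ndarray:
    """Zero the disabled feature groups of a (21, 90) window or (n, 1890) batch."""
    keep = mask.keep_vector()
    arr = np.asarray(window, dtype=float)
    if arr.ndim >= 1 and arr.shape[-1] == WINDOW_SIZE:
        return arr * np.tile(keep, WINDOW)
    return arr * keep


class WindowEncoder:
    """Transformer from variant tables to flattened (n, 1890) window matrices.

    Stateless in the sklearn sense (``fit`` only validates); ``transform``
    takes a DataFrame with columns ``gene, position, wt, mut`` and returns the
    encoded windows, applying the configured feature mask.

    Parameters
    ----------
    genes
        Mapping from gene id to :class:`GeneData`.
    mask
        Optional :class:`FeatureMask` applied after encoding.
    flatten
        Return (n, 1890) when True, else (n, 21, 90).
    """

    def __init__(
        self,
        genes: Mapping[str, GeneData],
        mask: FeatureMask | None = None,
        half_width: int = HALF_WIDTH,
        flatten: bool = True,
    ) -> None:
        self.genes = genes
        self.mask = mask
        self.half_width = half_width
        self.flatten = flatten

    def get_params(self, deep: bool = True) -> dict:
        return {
            "genes": self.genes,
            "mask": self.mask,
            "half_width": self.half_width,
            "flatten": self.flatten,
        }

    def set_params(self, **params) -> "WindowEncoder":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "WindowEncoder":
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        required = {"gene", "position", "wt", "mut"}
        missing = required - set(X.columns)
        if missing:
            raise ValueError(f"variant table missing columns: {sorted(missing)}")
        n = len(X)
        width = 2 * self.half_width + 1
        out = np.zeros((n, width, N_FEATURES))
        for i, row in enumerate(X.itertuples(index=False)):
            gd = self.genes.get(row.gene)
            if gd is None:
                raise KeyError(f"no gene data for {row.gene!r}")
            out[i] = encode_window(gd, int(row.position), row.wt, row.mut, self.half_width)
        if self.mask is not None:
            out = out * self.mask.keep_vector()
        if self.flatten:
            return out.reshape(n, -1)
        return out

    def fit_transform(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).transform(X)
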