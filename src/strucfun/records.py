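"""The protein record flowing through the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ProteinRecord:
    """One protein: identifier, sequence, and whatever stages have attached.

    Attributes
    ----------
    id : str
        Unique identifier.
    sequence : str
        One-letter residue codes.
    coords : (L, 3) float array, optional
        Per-residue 3D coordinates in Angstroms (C-alpha / bead positions).
    contact_map : object, optional
        A :class:`strucfun.structures.ContactMap` once built.
    labels : (T,) int array, optional
        Binary indicator over the label space.
    motif_indices : dict[int, np.ndarray]
        Ground-truth functional-site residue indices per term index
        (synthetic data only; used for saliency evaluation).
    """

    id: str
    sequence: str
    coords: np.ndarray | None = None
    contact_map: object | None = None
    labels: np.ndarray | None = None
    motif_indices: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)
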