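"""Concatemer geometry: monomer chain, tether position, labeling."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Concatemer:
    """A linear chain of VWF monomers tethered to the chamber wall.

    The tether attaches at ``tether_monomer_index`` (0-based along the chain).
    The longer arm of the chain trails downstream in flow and bears tension;
    the shorter arm carries none.  ``fluorophores_per_monomer`` holds the
    integer label count of each monomer (mean degree of labeling 0.67).
    """

    n_monomers: int
    tether_monomer_index: int = 0
    fluorophores_per_monomer: np.ndarray | None = None
    contour_length_per_monomer: float = 60.0  # nm

    def __post_init__(self) -> None:
        if self.n_monomers < 1:
            raise ValueError("n_monomers must be >= 1")
        if not 0 <= self.tether_monomer_index < self.n_monomers:
            raise ValueError("tether_monomer_index out of range")
        if self.contour_length_per_monomer <= 0:
            raise ValueError("contour_length_per_monomer must be positive")
        if self.fluorophores_per_monomer is not None:
            arr = np.asarray(self.fluorophores_per_monomer)
            if arr.shape != (self.n_monomers,):
                raise ValueError("fluorophores_per_monomer must have one entry per monomer")
            if (arr < 0).any():
                raise ValueError("fluorophore counts must be non-negative")
            self.fluorophores_per_monomer = arr

    @property
    def n_downstream(self) -> int:
        """Monomers in the load-bearing (longer) arm, tethered monomer included."""
        t = self.tether_monomer_index
        return max(self.n_monomers - t, t + 1)

    @property
    def n_upstream(self) -> int:
        """Monomers on the short side of the tether; they bear no tension."""
        return self.n_monomers - self.n_downstream

    @property
    def contour_length_um(self) -> float:
        """Full contour length in μm."""
        return self.n_monomers * self.contour_length_per_monomer / 1000.0

    @property
    def total_fluorophores(self) -> int:
        if self.fluorophores_per_monomer is None:
            raise ValueError("concatemer has no labeling information")
        return int(np.sum(self.fluorophores_per_monomer))
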