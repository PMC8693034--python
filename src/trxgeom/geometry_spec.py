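"""Discretization grids for the four pairwise geometries.

Bin layout (shared no-contact convention):

* distance d: 37 bins; bin 0 = no contact (d >= 20 A or undefined),
  bins 1..36 cover [2, 20) A in 0.5 A steps: bin b = [2 + 0.5(b-1), 2 + 0.5b).
* omega, theta: 25 bins; bin 0 = no contact, bins 1..24 are 15 degree bins
  tiling [-180, 180).
* phi: 13 bins; bin 0 = no contact, bins 1..12 are 15 degree bins tiling
  [0, 180]; the closed upper edge 180 falls in the top bin.

The no-contact bin is keyed on d alone and shared by all four geometries:
orientations are undefined without spatial proximity, so a pair at
d >= 20 A gets label 0 in every channel group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GeometrySpec:
    d_min: float = 2.0
    d_max: float = 20.0
    d_step: float = 0.5
    angle_step: float = 15.0
    contact_cutoff: float = 8.0  # contacts: d <= 8 A

    @property
    def n_dist_bins(self) -> int:
        return int(round((self.d_max - self.d_min) / self.d_step)) + 1  # 37

    @property
    def n_omega_bins(self) -> int:
        return int(round(360.0 / self.angle_step)) + 1  # 25

    @property
    def n_theta_bins(self) -> int:
        return self.n_omega_bins

    @property
    def n_phi_bins(self) -> int:
        return int(round(180.0 / self.angle_step)) + 1  # 13

    @property
    def n_template_channels(self) -> int:
        """One-hot width of an encoded template: 37 + 25 + 25 + 13 = 100."""
        return (
            self.n_dist_bins
            + self.n_omega_bins
            + self.n_theta_bins
            + self.n_phi_bins
        )

    # --- label maps ----------------------------------------------------

    def dist_labels(self, d: np.ndarray) -> np.ndarray:
        """Distance labels; 0 for d >= d_max, else floor((d-2)/0.5)+1 in [1,36]."""
        d = np.asarray(d, dtype=float)
        lab = np.floor((d - self.d_min) / self.d_step).astype(np.int64) + 1
        lab = np.clip(lab, 1, self.n_dist_bins - 1)
        lab[d >= self.d_max] = 0
        return lab

    def signed_angle_labels(self, a: np.ndarray) -> np.ndarray:
        """omega/theta labels on [-180, 180), bins 1..24; caller applies mask."""
        a = np.asarray(a, dtype=float)
        wrapped = np.mod(a + 180.0, 360.0) - 180.0
        lab = np.floor((wrapped + 180.0) / self.angle_step).astype(np.int64) + 1
        return np.clip(lab, 1, self.n_omega_bins - 1)

    def planar_angle_labels(self, a: np.ndarray) -> np.ndarray:
        """phi labels on [0, 180], bins 1..12; 180 goes to the top bin."""
        a = np.asarray(a, dtype=float)
        lab = np.floor(a / self.angle_step).astype(np.int64) + 1
        return np.clip(lab, 1, self.n_phi_bins - 1)

    # --- bin geometry --------------------------------------------------

    def dist_bin_midpoints(self) -> np.ndarray:
        """Midpoints of the 36 contact distance bins (index 1..36)."""
        lo = self.d_min + self.d_step * np.arange(self.n_dist_bins - 1)
        return lo + self.d_step / 2.0

    def contact_bin_slice(self) -> slice:
        """Distance bins with upper edge <= the 8 A contact cutoff.

        Bins 1..12 cover [2, 8) A, so summing them gives P(d <= 8 A) up to
        the grid resolution.
        """
        n = int(round((self.contact_cutoff - self.d_min) / self.d_step))
        return slice(1, 1 + n)


DEFAULT_SPEC = GeometrySpec()
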