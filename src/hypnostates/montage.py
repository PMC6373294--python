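"""Scalp montage: extended 10/20 channel labels, flattened sensor positions
and the anterior/posterior regions of interest used for ROI-level
connectivity summaries.

The native layout has 63 scalp channels (a 64-electrode cap referenced at Cz
with the two EOG channels removed).  Positions come from the standard 10/05
idealised head and are projected onto the unit disc with an azimuthal
equidistant projection (nose up, right ear to the right).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Montage",
    "make_montage",
    "ANTERIOR_ROI",
    "POSTERIOR_ROI",
    "CHANNELS_63",
]

#: 19 frontal / fronto-central channels forming the anterior ROI.
ANTERIOR_ROI: tuple[str, ...] = (
    "AFz", "Fz", "FCz", "AF7", "AF3", "F1", "FC1", "F3", "FC3", "F5",
    "F7", "AF8", "AF4", "F2", "FC2", "F4", "FC4", "F6", "F8",
)

#: 20 centro-parietal / parietal / occipital channels forming the posterior ROI.
POSTERIOR_ROI: tuple[str, ...] = (
    "CPz", "Pz", "POz", "Oz", "P1", "P2", "PO3", "PO4", "O1", "O2",
    "P3", "P5", "P7", "P4", "P6", "P8", "CP3", "CP1", "CP2", "CP4",
)

#: Remaining scalp channels completing the 63-channel layout.
_OTHER_63: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "FT7", "FT8", "T7", "T8", "TP7", "TP8",
    "C1", "C2", "C3", "C4", "C5", "C6", "Cz", "CP5", "CP6",
    "PO7", "PO8", "FT9", "FT10", "TP9", "TP10",
)

CHANNELS_63: tuple[str, ...] = ANTERIOR_ROI + POSTERIOR_ROI + _OTHER_63


class MontageError(ValueError):
    """Raised for unsupported channel counts or inconsistent ROI/label sets."""


@dataclass(frozen=True)
class Montage:
    """Channel labels with 2D unit-disc positions and ROI membership.

    Attributes
    ----------
    labels : tuple of str
        Unique channel names.
    positions : ndarray, shape (n_channels, 2)
        Flattened sensor coordinates, all inside the unit disc.  Unitless;
        +x is the subject's right, +y the nose.
    roi_anterior, roi_posterior : tuple of str
        Label subsets defining the two ROIs; every member must appear in
        ``labels``.
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    roi_anterior: tuple[str, ...] = ANTERIOR_ROI
    roi_posterior: tuple[str, ...] = POSTERIOR_ROI

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        if len(set(labels)) != len(labels):
            raise MontageError("channel labels must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(labels), 2):
            raise MontageError(
                f"positions shape {pos.shape} does not match {len(labels)} labels"
            )
        if not np.all(np.isfinite(pos)):
            raise MontageError("positions must be finite")
        if np.any(np.linalg.norm(pos, axis=1) > 1.0 + 1e-9):
            raise MontageError("positions must lie within the unit disc")
        missing = [l for roi in (self.roi_anterior, self.roi_posterior)
                   for l in roi if l not in labels]
        if missing:
            raise MontageError(f"ROI labels not present in montage: {missing}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "roi_anterior", tuple(self.roi_anterior))
        object.__setattr__(self, "roi_posterior", tuple(self.roi_posterior))

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, names) -> np.ndarray:
        """Indices of ``names`` within the montage labels."""
        lut = {l: i for i, l in enumerate(self.labels)}
        missing = [n for n in names if n not in lut]
        if missing:
            raise MontageError(f"channels not in montage: {missing}")
        return np.array([lut[n] for n in names], dtype=int)

    def anterior_idx(self) -> np.ndarray:
        return self.index(self.roi_anterior)

    def posterior_idx(self) -> np.ndarray:
        return self.index(self.roi_posterior)

    def subset(self, names) -> "Montage":
        """Montage restricted (and reordered) to ``names``.

        ROI membership is intersected with the surviving labels.
        """
        idx = self.index(names)
        keep = set(names)
        return Montage(
            labels=tuple(names),
            positions=self.positions[idx],
            roi_anterior=tuple(l for l in self.roi_anterior if l in keep),
            roi_posterior=tuple(l for l in self.roi_posterior if l in keep),
        )


def _standard_positions(labels) -> np.ndarray:
    """2D unit-disc positions for extended 10/20 labels.

    Uses the idealised 10/05 electrode coordinates shipped with MNE and an
    azimuthal equidistant projection about the vertex.
    """
    import mne

    try:
        std = mne.channels.make_standard_montage("colin27_1005")
    except ValueError:  # pragma: no cover - pre-rename MNE
        std = mne.channels.make_standard_montage("standard_1005")
    ch_pos = std.get_positions()["ch_pos"]
    missing = [l for l in labels if l not in ch_pos]
    if missing:
        raise MontageError(f"no standard position for channels: {missing}")
    xyz = np.array([ch_pos[l] for l in labels], dtype=float)
    # centre on the head origin, then polar angle from vertex + azimuth
    r = np.linalg.norm(xyz, axis=1)
    theta = np.arccos(np.clip(xyz[:, 2] / r, -1.0, 1.0))  # 0 at vertex
    az = np.arctan2(xyz[:, 0], xyz[:, 1])  # 0 toward nose, +pi/2 to the right
    rho = theta / theta.max() * 0.95
    return np.column_stack([rho * np.sin(az), rho * np.cos(az)])


def make_montage(n_channels: int = 63, labels=None, positions=None) -> Montage:
    """Build the native 63-channel montage, or a custom one.

    Parameters
    ----------
    n_channels : int
        Channel count.  63 is supported natively; any other count requires
        explicit ``labels`` and ``positions``.
    labels, positions : optional
        Custom label list and (n, 2) unit-disc coordinate table.

    Raises
    ------
    MontageError
        If ``n_channels`` is unsupported and no custom table is given.
    """
    if labels is not None and positions is not None:
        if len(labels) != n_channels:
            raise MontageError("custom label table length != n_channels")
        keep = set(labels)
        return Montage(
            labels=tuple(labels),
            positions=np.asarray(positions, dtype=float),
            roi_anterior=tuple(l for l in ANTERIOR_ROI if l in keep),
            roi_posterior=tuple(l for l in POSTERIOR_ROI if l in keep),
        )
    if n_channels != 63:
        raise MontageError(
            f"{n_channels} channels not supported natively; supply a custom "
            "label/position table"
        )
    return Montage(labels=CHANNELS_63, positions=_standard_positions(CHANNELS_63))
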