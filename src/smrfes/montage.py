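"""Channel montage: the 32-electrode layout and neighbor sets.

The default montage matches a 32-channel active-electrode cap with a
motor-cortex-dense layout.  Neighbor sets drive the discrete
small-Laplacian spatial filter; they list the nearest recorded
electrodes only (the cap omits some 10-10 positions, so a few sets are
sparse).
"""

from __future__ import annotations

CHANNELS_32: tuple[str, ...] = (
    "AFz", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC3", "FC1", "FC2", "FC4", "FC6",
    "T7", "C5", "C3", "Cz", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CPz", "CP4", "CP6", "TP8",
    "P3", "P4", "PO3", "PO4", "O1", "O2",
)

FRONTAL_CHANNELS: tuple[str, ...] = ("AFz", "F7", "F3", "Fz", "F4", "F8")

#: Left-hemisphere sensorimotor channels (contralateral for a right-hand task).
LEFT_MOTOR_CHANNELS: tuple[str, ...] = ("FC5", "FC3", "FC1", "C5", "C3", "CP5", "CP3")

DEFAULT_NEIGHBORS: dict[str, tuple[str, ...]] = {
    "AFz": ("F3", "Fz", "F4"),
    "F7": ("F3", "FC5", "T7"),
    "F3": ("F7", "Fz", "FC5", "FC3", "FC1"),
    "Fz": ("F3", "F4", "FC1", "FC2", "AFz"),
    "F4": ("Fz", "F8", "FC2", "FC4", "FC6"),
    "F8": ("F4", "FC6", "T8"),
    "FC5": ("F7", "F3", "FC3", "T7", "C5"),
    "FC3": ("F3", "FC5", "FC1", "C5", "C3"),
    "FC1": ("F3", "Fz", "FC3", "C3", "Cz"),
    "FC2": ("Fz", "F4", "FC4", "Cz", "C4"),
    "FC4": ("F4", "FC2", "FC6", "C4", "C6"),
    "FC6": ("F4", "F8", "FC4", "C6", "T8"),
    "T7": ("F7", "FC5", "C5", "TP7"),
    "C5": ("FC5", "FC3", "T7", "C3", "CP5", "CP3"),
    "C3": ("FC3", "FC1", "C5", "Cz", "CP5", "CP3"),
    "Cz": ("FC1", "FC2", "C3", "C4", "CPz"),
    "C4": ("FC2", "FC4", "Cz", "C6", "CP4", "CP6"),
    "C6": ("FC4", "FC6", "C4", "T8", "CP6"),
    "T8": ("F8", "FC6", "C6", "TP8"),
    "TP7": ("T7", "C5", "CP5"),
    "CP5": ("C5", "C3", "TP7", "CP3", "P3"),
    "CP3": ("C5", "C3", "CP5", "CPz", "P3"),
    "CPz": ("C3", "Cz", "C4", "CP3", "CP4"),
    "CP4": ("C4", "C6", "CPz", "CP6", "P4"),
    "CP6": ("C4", "C6", "CP4", "TP8", "P4"),
    "TP8": ("T8", "C6", "CP6"),
    "P3": ("CP5", "CP3", "PO3"),
    "P4": ("CP4", "CP6", "PO4"),
    "PO3": ("P3", "O1"),
    "PO4": ("P4", "O2"),
    "O1": ("PO3", "O2"),
    "O2": ("PO4", "O1"),
}


def channel_index(labels: list[str] | tuple[str, ...]) -> dict[str, int]:
    """Map each channel label to its row index."""
    return {label: i for i, label in enumerate(labels)}
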