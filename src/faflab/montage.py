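"""Default 64-channel montage and fronto-central topographic weights.

The label set is a 10-10 style naming that contains the ten fronto-central
measurement electrodes (FC1-4, FCz, C1-4, Cz) and the two mastoids (M1, M2)
used for offline re-referencing. Topographic weights scale the simulated
N1/P2 components: strongest fronto-centrally, fading toward posterior sites,
exactly zero at the mastoids (so vertex-recorded and mastoid-re-referenced
noise-free epochs agree).
"""

from __future__ import annotations

DEFAULT_64 = [
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "M1", "M2",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
]

#: electrodes at which ERP components are measured
MEASUREMENT_ELECTRODES = ["FC1", "FC2", "FC3", "FC4", "FCz",
                          "C1", "C2", "C3", "C4", "Cz"]

MASTOIDS = ["M1", "M2"]

#: frontal sites that receive simulated blink artifacts
FRONTAL_CHANNELS = ["Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8"]

# explicit weights for the measurement sites; FCz is exactly 1 so that
# noise-free peak measurements there recover the generative amplitudes.
_MEASUREMENT_WEIGHTS = {
    "FCz": 1.00, "FC1": 0.95, "FC2": 0.95, "FC3": 0.90, "FC4": 0.90,
    "Cz": 0.85, "C1": 0.80, "C2": 0.80, "C3": 0.75, "C4": 0.75,
}

_PREFIX_WEIGHTS = [
    ("Fp", 0.55), ("AF", 0.60), ("FT", 0.55), ("FC", 0.90), ("F", 0.70),
    ("TP", 0.25), ("CP", 0.55), ("C", 0.75), ("T", 0.30),
    ("PO", 0.15), ("P", 0.30), ("O", 0.10), ("I", 0.05), ("M", 0.0),
]


def topographic_weight(label: str) -> float:
    """Fronto-central scaling of the evoked components at ``label``."""
    if label in _MEASUREMENT_WEIGHTS:
        return _MEASUREMENT_WEIGHTS[label]
    for prefix, w in _PREFIX_WEIGHTS:
        if label.startswith(prefix):
            return w
    return 0.3


def topographic_weights(labels: list[str]):
    return [topographic_weight(lab) for lab in labels]
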