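"""Pinned 32-channel montage (10-20 extended layout).

The recording cap has 30 scalp electrodes plus the two mastoids (M1, M2)
used for offline re-referencing.  The exact label set of the vendor cap is
not published anywhere, so this canonical list is a convention pinned once
and used by every stage: the (electrode, frequency) feature index and hence
the 4800-column cohort matrix are deterministic only because this order is.
"""

from __future__ import annotations

#: 30 scalp channels, anterior to posterior, left to right.
SCALP_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

MASTOIDS: tuple[str, str] = ("M1", "M2")

#: Full 32-channel acquisition montage (scalp + mastoids).
ALL_CHANNELS: tuple[str, ...] = SCALP_CHANNELS + MASTOIDS

#: Midline-anterior cluster where the pain-related beta/gamma effect peaks.
FRONTOCENTRAL: tuple[str, ...] = ("F3", "Fz", "F4", "FC3", "FCz", "FC4", "Cz")

#: Occipital cluster carrying the eyes-closed alpha peak.
OCCIPITAL: tuple[str, ...] = ("O1", "Oz", "O2")

#: Frontal channels used by the eye-blink IC criteria.
FRONTAL: tuple[str, ...] = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")


def channel_indices(channels: list[str] | tuple[str, ...], labels) -> list[int]:
    """Indices of `labels` within `channels`; unknown label raises KeyError."""
    lookup = {c: i for i, c in enumerate(channels)}
    return [lookup[lab] for lab in labels]
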