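"""Electrode montage of the 14-channel consumer EEG headset (10/20 positions)."""

from __future__ import annotations

#: Channel order as exported by the acquisition software.
CHANNELS: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Frontal channels closest to the eyes; they carry the EOG artifact and are
#: the "active channels" every feature bank is built on.  The order here fixes
#: the channel-major layout of feature ids.
ACTIVE_CHANNELS: tuple[str, ...] = ("AF3", "F7", "F8", "AF4")

#: Occipital channels over visual cortex, where the SSVEP response is strongest.
OCCIPITAL_CHANNELS: tuple[str, ...] = ("O1", "O2")

#: Left-hemisphere electrodes (the remainder are right-hemisphere).
LEFT_CHANNELS: frozenset[str] = frozenset({"AF3", "F7", "F3", "FC5", "T7", "P7", "O1"})


def channel_index(name: str, channels: tuple[str, ...] = CHANNELS) -> int:
    """Index of ``name`` in ``channels``, with a helpful error."""
    try:
        return channels.index(name)
    except ValueError:
        raise KeyError(f"unknown channel {name!r}; montage has {list(channels)}") from None
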