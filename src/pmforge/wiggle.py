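"""fixedStep wiggle output for evidence tracks (genome-browser ready)."""

from __future__ import annotations

import math
from typing import Iterable

from .records import WiggleTrack


def write_wiggle(tracks: Iterable[WiggleTrack], path) -> None:
    """Write tracks in the fixedStep wiggle dialect, one declaration per track."""
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks to write")
    with open(path, "w") as fh:
        for track in tracks:
            for v in track.values:
                if not math.isfinite(v):
                    raise ValueError(
                        f"track {track.target_id}: non-finite value {v!r} "
                        "(wiggle has no NaN/inf)"
                    )
            if track.name:
                fh.write(f'track type=wiggle_0 name="{track.name}"\n')
            fh.write(
                f"fixedStep chrom={track.target_id} start={track.start} "
                f"step={track.step} span={track.span}\n"
            )
            for v in track.values:
                fh.write(f"{v:g}\n")
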