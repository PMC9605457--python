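"""Plain-text I/O: the two-column recording CSV dialect and label tables.

Recording files carry one comment header line::

    # fs=500 channel=BPW subject=s001 session=M0
    time_s,amplitude
    0.000,1.234
    ...
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .preprocess import PulseRecording


def write_recording_csv(rec: PulseRecording, path: str | Path) -> None:
    path = Path(path)
    t = np.arange(len(rec.samples)) / rec.fs
    header = (
        f"# fs={rec.fs:g} channel={rec.channel} "
        f"subject={rec.subject_id} session={rec.session}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        fh.write("time_s,amplitude\n")
        for ti, si in zip(t, rec.samples):
            fh.write(f"{ti:.6f},{si:.8g}\n")


def read_recording_csv(path: str | Path) -> PulseRecording:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("#"):
        raise InvalidParameterError(f"{path}: missing '# fs=...' header line")
    meta = {}
    for token in first.lstrip("#").split():
        if "=" in token:
            key, value = token.split("=", 1)
            meta[key] = value
    if "fs" not in meta:
        raise InvalidParameterError(f"{path}: header lacks fs=<Hz>")
    frame = pd.read_csv(path, comment="#")
    return PulseRecording(
        samples=frame["amplitude"].to_numpy(dtype=float),
        fs=float(meta["fs"]),
        channel=meta.get("channel", "BPW"),
        subject_id=meta.get("subject", ""),
        session=meta.get("session", "M0"),
    )


def write_labels_csv(labels: pd.DataFrame, path: str | Path) -> None:
    labels.to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
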