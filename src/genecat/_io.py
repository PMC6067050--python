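"""Small I/O helpers shared across modules: gzip-transparent text opening."""

from __future__ import annotations

import gzip
import io
from pathlib import Path


def open_text(path, mode: str = "rt"):
    """Open a plain or gzip-compressed text file transparently.

    Detection is by magic bytes for reading and by a ``.gz`` suffix for
    writing.
    """
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as probe:
            magic = probe.read(2)
        if magic == b"\x1f\x8b":
            return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
        return open(path, mode, encoding="utf-8")
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, mode.replace("t", "") + "b"),
                                encoding="utf-8")
    return open(path, mode, encoding="utf-8")
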