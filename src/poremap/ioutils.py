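"""Atomic file writes and PDB/TIFF/text I/O helpers."""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

__all__ = ["atomic_write"]


@contextmanager
def atomic_write(path: str | Path):
    """Write-then-rename: yields a temporary path in the target directory,
    atomically renamed onto ``path`` on success, removed on failure.

    Reruns therefore never leave a half-written output behind.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    tmp_path = Path(tmp)
    try:
        yield tmp_path
        os.replace(tmp_path, path)
    except BaseException:
        tmp_path.unlink(missing_ok=True)
        raise
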