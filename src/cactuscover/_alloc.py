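"""glibc allocator tuning for large-raster workloads.

The pipeline allocates and frees many ~100 MB image buffers.  With glibc's
defaults each of those goes through mmap/munmap, so every fresh buffer pays
its full soft-page-fault cost again; on kernels/containers where faulting is
expensive this dominates runtime.  Keeping large blocks in the process heap
(no mmap, no trim) lets freed raster buffers be reused immediately.  The
trade-off is that resident memory stays near its high-water mark, which is
acceptable for this package's working sets.

No-op on platforms without glibc's ``mallopt``.
"""

from __future__ import annotations

import ctypes

_M_TRIM_THRESHOLD = -1
_M_TOP_PAD = -2
_M_MMAP_MAX = -4


def tune_allocator() -> bool:
    try:
        libc = ctypes.CDLL("libc.so.6")
        ok = libc.mallopt(_M_MMAP_MAX, 0)
        ok &= libc.mallopt(_M_TRIM_THRESHOLD, 2**31 - 1)
        libc.mallopt(_M_TOP_PAD, 1 << 26)
        return bool(ok)
    except Exception:
        return False
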