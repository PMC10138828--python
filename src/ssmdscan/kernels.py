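"""Shift-matrix kernel library for strand-pair arrangement classification.

Two β-strands of equal length ``RES`` can pack parallel or antiparallel,
and in either orientation the residue registers may be offset by an
integer shift ``s``.  Each idealized arrangement maps to a binary
``RES × RES`` template ("kernel"): the entry (i, j) is 1 when residue
``i`` of the first strand faces residue ``j`` of the second.  With
0-based residue indices and ``n = RES - 1`` the four families are

* ``P+``: ones where ``j - i = s``      (parallel, positive shift)
* ``P-``: ones where ``i - j = s``      (parallel, negative shift)
* ``A+``: ones where ``i + j = n + s``  (antiparallel, positive shift)
* ``A-``: ones where ``i + j = n - s``  (antiparallel, negative shift)

The full library stacks all four families for every shift ``s`` in
``[0, RES)``, giving exactly ``4 * RES`` kernels indexed ``k``:
family ``m = k // RES`` in the order above, shift ``s = k % RES``.
A kernel in family P± or A± with shift ``s`` has ``RES - s`` ones.

At shift 0 the two parallel kernels coincide (the identity matrix) and
the two antiparallel kernels coincide (the anti-diagonal); both indices
are kept so the library size is always ``4 * RES``, and downstream
argmax ties resolve to the lowest index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Family codes in library order.
FAMILIES = ("P+", "P-", "A+", "A-")

#: Reporting class for each family: both parallel families report as "P",
#: the antiparallel families keep their sign.
REPORT_CLASS = {"P+": "P", "P-": "P", "A+": "AP+", "A-": "AP-"}


@dataclass(frozen=True)
class KernelLibrary:
    """Stack of 4·RES binary shift matrices with orientation/shift labels.

    Attributes
    ----------
    res : int
        Strand length (residues per molecule).
    stack : numpy.ndarray
        Array of shape ``(4 * res, res, res)``, dtype uint8.
    labels : tuple[tuple[str, int], ...]
        Per-kernel ``(orientation, shift)`` with orientation in
        ``{"P+", "P-", "A+", "A-"}``.
    """

    res: int
    stack: np.ndarray = field(repr=False)
    labels: tuple[tuple[str, int], ...] = field(repr=False)

    def __len__(self) -> int:
        return self.stack.shape[0]

    def __getitem__(self, k: int) -> np.ndarray:
        return self.stack[k]

    def report_class(self, k: int) -> tuple[str, int]:
        """Reporting category ("P", "AP+" or "AP-") and shift of kernel k."""
        orientation, shift = self.labels[k]
        return REPORT_CLASS[orientation], shift


def build_kernel_library(res: int) -> KernelLibrary:
    """Build the library of 4·``res`` binary shift matrices.

    Parameters
    ----------
    res : int
        Residues per molecule; must be ≥ 2.

    Returns
    -------
    KernelLibrary
    """
    if res < 2:
        raise ValueError(f"kernel library needs res >= 2, got {res}")
    n = res - 1
    i, j = np.meshgrid(np.arange(res), np.arange(res), indexing="ij")
    stack = np.zeros((4 * res, res, res), dtype=np.uint8)
    labels: list[tuple[str, int]] = []
    for k in range(4 * res):
        family, s = _partition(k, res)
        if family == "P+":
            mask = (j - i) == s
        elif family == "P-":
            mask = (i - j) == s
        elif family == "A+":
            mask = (i + j) == n + s
        else:  # A-
            mask = (i + j) == n - s
        stack[k][mask] = 1
        labels.append((family, s))
    return KernelLibrary(res=res, stack=stack, labels=tuple(labels))


def _partition(k: int, res: int) -> tuple[str, int]:
    return FAMILIES[k // res], k % res


def kernel_class(k: int, res: int) -> tuple[str, int]:
    """Map a kernel index to its ``(orientation, shift)`` label.

    ``orientation`` is one of ``{"P+", "P-", "A+", "A-"}``; use
    :data:`REPORT_CLASS` to collapse to the reporting categories
    P / AP+ / AP-.
    """
    if not 0 <= k < 4 * res:
        raise ValueError(f"kernel index {k} out of range [0, {4 * res})")
    return _partition(k, res)


def kernel_labels_table(lib: KernelLibrary):
    """Per-kernel label table: columns k, orientation, shift, nnz."""
    import pandas as pd

    rows = [
        {
            "k": k,
            "orientation": lib.labels[k][0],
            "shift": lib.labels[k][1],
            "nnz": int(lib.stack[k].sum()),
        }
        for k in range(len(lib))
    ]
    return pd.DataFrame(rows)
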