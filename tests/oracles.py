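"""Independent reference implementations used only to cross-check results.

These deliberately avoid the package's own superposition code path: the
pairwise RMSD oracle is Horn/Kearsley's quaternion characteristic-polynomial
method, and the ensemble oracle composes scipy's ``Rotation.align_vectors``
with an explicit mean / explicit per-conformer RMSD evaluation.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def quaternion_rmsd(reference: np.ndarray, moving: np.ndarray) -> float:
    """Optimal-superposition RMSD via the Kearsley 4×4 eigenvalue problem."""
    ref = np.asarray(reference, float)
    mov = np.asarray(moving, float)
    n = ref.shape[0]
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    s = mov_c.T @ ref_c
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    g = np.sum(ref_c**2) + np.sum(mov_c**2)
    return float(np.sqrt(max(g - 2.0 * lam, 0.0) / n))


def brute_force_rmsd_to_mean(coords: np.ndarray) -> float:
    """Ensemble RMSD-to-mean computed step by explicit step.

    Each conformer is superimposed onto the first with scipy, the mean
    coordinates are formed, and each conformer's RMSD to the mean is averaged.
    """
    coords = np.asarray(coords, float)
    ref = coords[0]
    ref_c = ref - ref.mean(axis=0)
    fitted = [ref.copy()]
    for conf in coords[1:]:
        mov_c = conf - conf.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_c, mov_c)
        fitted.append(rot.apply(mov_c) + ref.mean(axis=0))
    fitted = np.asarray(fitted)
    mean = fitted.mean(axis=0)
    rmsds = [
        np.sqrt(np.mean(np.sum((f - mean) ** 2, axis=1))) for f in fitted
    ]
    return float(np.mean(rmsds))
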