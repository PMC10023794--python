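"""Independent straight-line reference implementation of the component
decomposition, used only to cross-check the main path.

Deliberately unoptimized: plain eigendecomposition, an explicit recursive
module split with Python lists, and the level formulas applied verbatim.
It shares only the documented sign/zero conventions with the main code
(they are part of the method definition), not any code.
"""

import numpy as np


def brute_force_components(C):
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w = w[order]
    V = V[:, order].copy()
    for i in range(n):
        s = V[:, i].sum()
        if abs(s) > 1e-12:
            if s < 0:
                V[:, i] = -V[:, i]
        else:
            j = int(np.abs(V[:, i]).argmax())
            if V[j, i] < 0:
                V[:, i] = -V[:, i]
    modules = [list(range(n))]
    H = []
    for level in range(1, n + 1):
        if level > 1:
            if len(modules) < n:
                refined = []
                for mod in modules:
                    pos = [r for r in mod if V[r, level - 1] >= 0]
                    neg = [r for r in mod if V[r, level - 1] < 0]
                    for part in (pos, neg):
                        if part:
                            refined.append(part)
                modules = refined
            else:
                modules = [[r] for r in range(n)]
        m_count = len(modules)
        p = sum(abs(len(mod) - n / m_count) for mod in modules) / n
        H.append(w[level - 1] ** 2 * m_count * (1.0 - p) / n)
    h_in = H[0] / n
    h_se = sum(H[1:]) / n
    regional_in = H[0] * V[:, 0] ** 2
    regional_se = np.zeros(n)
    for i in range(2, n + 1):
        regional_se += H[i - 1] * V[:, i - 1] ** 2
    return h_in, h_se, regional_in, regional_se
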