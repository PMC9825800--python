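"""Independent grid-search maximum-likelihood oracle.

Enumerates the (theta_yes, theta_no) simplex on a fixed grid and evaluates
the binomial log-likelihood directly; used to validate the constrained
analytic estimator without sharing any code path with it.
"""

import numpy as np


class GridOracle:
    def __init__(self, design, step=1e-3):
        t = np.arange(0.0, 1.0 + step / 2, step)
        ty, tn = np.meshgrid(t, t, indexing="ij")
        keep = ty + tn <= 1.0 + 1e-12
        self.ty, self.tn = ty[keep], tn[keep]
        a1, b1 = 1.0 - design.p1_no, design.p1_yes
        a2, b2 = 1.0 - design.p2_no, design.p2_yes
        self.lam1 = a1 * self.ty + b1 * self.tn
        self.lam2 = a2 * self.ty + b2 * self.tn
        with np.errstate(divide="ignore"):
            self.log_lam1 = np.log(self.lam1)
            self.log1m_lam1 = np.log1p(-self.lam1)
            self.log_lam2 = np.log(self.lam2)
            self.log1m_lam2 = np.log1p(-self.lam2)

    def _ll(self, y, n, log_lam, log1m_lam):
        out = np.zeros_like(log_lam)
        if y > 0:
            out = out + y * log_lam
        if n - y > 0:
            out = out + (n - y) * log1m_lam
        return out

    def best(self, y1, n1, y2, n2):
        """(theta_yes, theta_no, theta_inc, log_likelihood) of the grid max."""
        ll = self._ll(y1, n1, self.log_lam1, self.log1m_lam1) + self._ll(
            y2, n2, self.log_lam2, self.log1m_lam2
        )
        i = int(np.argmax(ll))
        return self.ty[i], self.tn[i], 1.0 - self.ty[i] - self.tn[i], float(ll[i])
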