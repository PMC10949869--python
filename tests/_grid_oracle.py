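"""Independent likelihood oracle shared by the allele-inference tests."""

import numpy as np

from vittabo.cohort import PhenotypeCounts


def grid_mle(counts: PhenotypeCounts, coarse=2e-3, fine=1e-4, window=4e-3):
    """Independent likelihood oracle: two-stage grid search on the simplex.

    A coarse scan locates the basin, then a local grid at the fine step
    pins the maximizer to `fine` resolution.
    """
    n = counts.as_array()

    def scan(pa_vals, pb_vals):
        pa, pb = np.meshgrid(pa_vals, pb_vals, indexing="ij")
        mask = pa + pb <= 1.0 + 1e-12
        pa, pb = pa[mask], pb[mask]
        po = 1.0 - pa - pb
        f = np.stack([po**2, pa**2 + 2*pa*po, pb**2 + 2*pb*po, 2*pa*pb], axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(n > 0, n * np.log(f), 0.0).sum(axis=1)
        ll[np.isnan(ll)] = -np.inf
        best = np.argmax(ll)
        return pa[best], pb[best]

    pa0, pb0 = scan(np.arange(0, 1 + coarse, coarse), np.arange(0, 1 + coarse, coarse))
    pa_vals = np.arange(max(0, pa0 - window), min(1, pa0 + window) + fine, fine)
    pb_vals = np.arange(max(0, pb0 - window), min(1, pb0 + window) + fine, fine)
    pa, pb = scan(pa_vals, pb_vals)
    return np.array([pa, pb, 1 - pa - pb])
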