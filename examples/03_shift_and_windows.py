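"""Estimate circular time shifts and time-window enrichment for one gene trio.

Builds noise-free cosinor profiles mimicking a CAM kinase: the two CAM
species peak in the night (2 h apart), the C3 ortholog in the day, then
estimates pairwise circular shifts on the half-hour grid and tests the
opposite-window abundance contrasts.
"""

import numpy as np

from camconverge import diel_screen as ds
from camconverge.core_io import CANONICAL_TIMES, DielProfile

t = np.asarray(CANONICAL_TIMES)


def cosinor(gene, species, phase, reps=3, seed=0):
    rng = np.random.default_rng(seed)
    log_mean = 2.0 + 1.5 * np.cos(2 * np.pi * (t - phase) / 24.0)
    eps = rng.normal(0, 0.1, size=(t.size, reps))
    return DielProfile(gene, species, t, np.exp(log_mean[:, None] + eps))


kf = cosinor("kf_ppck", "Kf", phase=18.0, seed=1)   # night peak
ac = cosinor("ac_ppck", "Ac", phase=19.5, seed=2)   # night peak, 1.5 h later
at = cosinor("at_ppck", "At", phase=7.0, seed=3)    # day peak

for name, a, b in [("Kf-Ac", kf, ac), ("Kf-At", kf, at), ("Ac-At", ac, at)]:
    est = ds.estimate_time_shift(a, b)
    print(f"shift {name}: {est.shift:+.1f} h (peak correlation {est.peak_correlation:.3f})")

enr = [ds.window_enrichment_test(p) for p in (kf, ac, at)]
ds.attach_qvalues(enr, fdr_threshold=0.01)
for e in enr:
    print(f"{e.gene_id}: enriched window = {e.enriched_window} "
          f"(q = {min(e.qvalues.values()):.2e})")
# The two CAM genes are enriched in the same night window with a small mutual
# shift; the C3 gene peaks in the opposite window ~11 h away - the pattern
# the screen's three criteria formalize.
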