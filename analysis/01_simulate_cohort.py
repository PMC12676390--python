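"""Generate the synthetic study cohort: feature tables with planted latent structure.

Writes a 100-subject cohort in which a sparse rank-1 factor couples the
morphometric and physiological blocks at rho = 0.7, plus covariates and the
ground truth, under results/cohort/.
"""

from pathlib import Path

import numpy as np

from neurolatent.synth import LatentCohortConfig, simulate_feature_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
OUT.mkdir(parents=True, exist_ok=True)

cfg = LatentCohortConfig(n_subjects=100, rho_true=0.7, noise_sd=0.5, seed=42)
physio, morph, covars, truth = simulate_feature_cohort(cfg)

physio.to_csv(OUT / "physio.tsv", sep="\t", float_format="%.10g")
morph.to_csv(OUT / "morph.tsv", sep="\t", float_format="%.10g")
covars.to_csv(OUT / "covars.tsv", sep="\t", float_format="%.10g")
np.savetxt(OUT / "truth_u_physio.txt", truth.u_true)
np.savetxt(OUT / "truth_v_morph.txt", truth.v_true)

emp = float(np.corrcoef(truth.z_scores, truth.w_scores)[0, 1])
print(f"cohort: n={cfg.n_subjects}, physio {physio.shape[1]} features, morph {morph.shape[1]} features")
print(f"planted latent correlation {cfg.rho_true}; empirical corr(z, w) = {emp:.3f}")
print(f"sparse supports: {np.count_nonzero(truth.u_true)} physio / {np.count_nonzero(truth.v_true)} morph")
print(f"written to {OUT}")
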