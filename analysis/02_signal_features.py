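"""Raw-signal demonstration: simulate multichannel recordings and extract features.

Builds a small set of subjects with four sites (M1, PM, S1, SubCort), plants
low-beta bursts and coupled channels, runs the preprocessing + feature pipeline,
and checks detection against the generator's ground truth. Writes the feature
table and a recovery summary under results/signal_demo/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from neurolatent.signals import (
    DEFAULT_BANDS, FeatureConfig, Recording, band_envelope, build_physio_features,
    detect_bursts, msc_coherence,
)
from neurolatent.synth import ArtifactSpec, BurstSpec, SignalSimConfig, simulate_coupled_channels, simulate_oscillatory_channel

OUT = Path(__file__).resolve().parents[1] / "results" / "signal_demo"
OUT.mkdir(parents=True, exist_ok=True)

N_SUBJECTS = 4
LOW_BETA = DEFAULT_BANDS[1]

recordings = {}
recovery = []
for i in range(N_SUBJECTS):
    chans, truths = [], []
    for j, site in enumerate(("M1", "PM", "S1", "SubCort")):
        cfg = SignalSimConfig(
            duration_s=30.0,
            bursts=(
                BurstSpec("low_beta", 16.0, rate_hz=0.2, duration_s=0.4, amplitude=1.2, baseline=0.3),
                BurstSpec("alpha", 9.5, rate_hz=0.1, duration_s=0.5, amplitude=0.8, baseline=0.2),
            ),
            line_amplitude=0.15,
            artifacts=ArtifactSpec(count=2, amplitude_mad=40.0, width_samples=5),
            seed=1000 + 10 * i + j,
        )
        rec, truth = simulate_oscillatory_channel(cfg, label=site)
        chans.append(rec)
        truths.append(truth)
    rec = Recording(
        samples=np.vstack([c.samples for c in chans]),
        fs=chans[0].fs,
        labels=[c.labels[0] for c in chans],
    )
    recordings[f"S{i:02d}"] = rec
    # M1 low beta: every planted high-amplitude interval should be hit by a
    # detected burst; at realistic burst time fractions the 75th-percentile
    # threshold legitimately detects additional baseline-level bursts too.
    env = band_envelope(rec, LOW_BETA)
    bs = detect_bursts(env[0], LOW_BETA, rec.fs)
    planted = truths[0].burst_intervals["low_beta"]
    hit = sum(
        any(b.start_s < e and b.end_s > s for b in bs.bursts) for s, e in planted
    )
    frac = sum(b.duration_s for b in bs.bursts) / rec.duration_s
    recovery.append(
        {"subject": f"S{i:02d}", "planted": len(planted), "planted_detected": hit,
         "total_detected": len(bs.bursts), "burst_time_fraction": round(frac, 3)}
    )

features = build_physio_features(recordings, FeatureConfig())
features.to_csv(OUT / "physio_features.tsv", sep="\t", float_format="%.10g")
rec_df = pd.DataFrame(recovery)
rec_df.to_csv(OUT / "burst_recovery.tsv", sep="\t", index=False)

cfg = SignalSimConfig(duration_s=60.0, bursts=(BurstSpec("low_beta", 16.0, amplitude=1.0),), seed=7)
pair, truth = simulate_coupled_channels(cfg, mix=0.5)
msc = msc_coherence(pair.samples[0], pair.samples[1], pair.fs, LOW_BETA)

print(f"feature table: {features.shape[0]} subjects x {features.shape[1]} features "
      f"({features.isna().sum().sum()} missing)")
print(rec_df.to_string(index=False))
print(f"coupled channels at equal shared/noise variance: MSC = {msc:.3f} "
      f"(analytic {truth.band_msc['low_beta']:.3f})")
print(f"written to {OUT}")
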