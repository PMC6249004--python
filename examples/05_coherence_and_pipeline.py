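"""Field-field coherence vs distance, and the end-to-end stage runner."""

import tempfile
from pathlib import Path

from metronome.config import AnalysisConfig, TaskConfig
from metronome.pipeline import run_pipeline
from metronome.studies import coherence_distance_study

coh = coherence_distance_study(seed=9, n_sessions=4)
print(f"phase-locking value vs electrode distance over "
      f"{coh['n_pairs']} pairs: slope {1000 * coh['slope_per_um']:.3f}/mm, "
      f"R^2 = {coh['r2']:.2f} (Spearman rho {coh['spearman_rho']:.2f})")
print("Coherence decays with separation: the gamma field is locally "
      "generated, not volume-conducted.\n")

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp) / "out"
    report = run_pipeline(
        TaskConfig(tempos_ms=(500.0,)),
        AnalysisConfig(n_permutations=200, n_iterations=5),
        Path(tmp) / "session.h5",
        ["simulate", "spectrogram", "bursts", "behavior", "report"],
        out, seed=11)
    print("pipeline summary (one synthetic session):")
    print(f"  median inter-burst interval: "
          f"{report['bursts']['median_ibi_t500']:.0f} ms")
    print(f"  fitted Weber fraction: "
          f"{report['behavior']['weber_fraction']:.3f}")
    print(f"  tables written: {sorted(p.name for p in out.glob('*.tsv'))}")
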