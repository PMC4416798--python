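"""Cross-validated decoding of one reduced synthetic subject.

Simulates a 4-session subject (3 cued, 1 uncued), preprocesses, and runs the
full leave-one-session-out pipeline: two-pass ICA, dipole/eye component
screening, wavelet features, sparse-count component selection, PCA and the
sparse logistic classifier.  Takes a couple of minutes; the full study
conditions are 10 sessions per subject (see the README's reproduction
section).
"""

import numpy as np

from gaitdecode import evaluate, pipeline, synth

gen = synth.GeneratorConfig(fs=512.0, n_sessions=4, n_cued=3)
raw = synth.simulate_subject(gen, seed=42, subject_id="demo")
print(f"simulated {len(raw)} sessions:",
      [r.condition for r in raw])

ana = pipeline.AnalysisConfig()
sessions = [pipeline.preprocess_recording(r, ana) for r in raw]
folds = evaluate.crossvalidate(sessions, seed=0,
                               n_components=ana.n_components,
                               n_restarts=ana.dipole_restarts,
                               ica_decim=ana.ica_decim)

cm = evaluate.pooled_cm(folds)
acc, sd = evaluate.classwise_accuracy(cm)
kap = evaluate.kappa(cm)
print(f"\npooled confusion matrix (rows = true constant/change):\n{cm}")
print(f"accuracy {acc:.1f} % +- {sd:.1f}, kappa {kap.k:.2f} "
      f"(lower bound {kap.k_lower:.2f}, significant: {kap.significant})")
for fr in folds:
    print(f"  fold {fr.fold} ({fr.condition}): "
          f"{len(fr.candidate_ids)} candidates after dipole/eye screening, "
          f"retained components {fr.retained_ids.tolist()}")
# With only 4 sessions the kappa bound is loose; the full 10-session cohort
# reaches the 70-85 % accuracy band with a clearly positive bound.
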