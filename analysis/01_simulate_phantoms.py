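"""Generate the study inputs: stimulation protocol, synthetic atlas and one
example phantom session per group.

Writes the protocol event table, the atlas structure table and the phantom
provenance under results/phantoms/. The 4D series themselves are kept in
memory downstream (regenerate them from the recorded seeds when needed).
"""
from pathlib import Path

import json

import thermofmri as tf
from thermofmri import pipeline as pl

OUT = Path(__file__).resolve().parents[1] / "results" / "phantoms"
OUT.mkdir(parents=True, exist_ok=True)

cfg = pl.RunConfig(scale="desk", seed=0)
atlas, protocol, baseline_model, rtx_model = pl.study_inputs(cfg)

protocol.to_tsv(OUT / "protocol_events.tsv")
atlas.structure_table.to_csv(OUT / "atlas_structures.tsv", sep="\t", index=False)

sessions = {}
for name, model in (("baseline", baseline_model), ("rtx", rtx_model)):
    series = tf.simulate_session(
        atlas, protocol, model, cfg.hrf, n_volumes=cfg.preset.n_stim_volumes, seed=cfg.seed
    )
    sessions[name] = series.provenance
(OUT / "session_provenance.json").write_text(json.dumps(sessions, indent=2, default=str))

print(f"protocol: {protocol.n_events} events over {protocol.duration:.0f} s, "
      f"temperatures {protocol.temperatures}")
print(f"atlas: {atlas.n_structures} structures, "
      f"{atlas.structure_table.functional_group.nunique()} functional groups, "
      f"{int(atlas.brain_mask.sum())} brain voxels")
print(f"responsive structures: {sorted(baseline_model.responsive_structures)}")
print(f"wrote {OUT}")
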