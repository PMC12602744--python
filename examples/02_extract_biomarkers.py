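"""Extract the 28 vocal biomarkers from one synthetic recording session.

Generates a subject's session (two phonations of each of the five
sustained vowels plus a speech-like item), builds the subject's formant
inventory from the vowel recordings, and prints the full feature vector
of the first /a/ phonation.  The articulation features (TVSA, QVSA, FCR)
are subject-level quantities broadcast onto each record.
"""

from vocalmarkers import PulseTrainSpec, generate_session
from vocalmarkers.features import build_formant_inventory, extract_record_features

base = PulseTrainSpec(f0=120.0, duration=1.5, jitter_rel=0.01, shimmer_rel=0.02,
                      hnr_db=18.0)
session = generate_session("subject01", class_label=1, base_spec=base, seed=7)
print(f"session: {len(session)} recordings "
      f"({[w.content for w in session].count('speech')} speech item)")

inventory = build_formant_inventory(session)
print("formant inventory (vowel -> F1, F2 in Hz):")
for vowel, (f1, f2) in sorted(inventory.entries.items()):
    print(f"  /{vowel}/  {f1:7.1f}  {f2:7.1f}")

features = extract_record_features(session[0], inventory)
print(f"\nfeature vector of {session[0].content}_1 "
      f"({sum(1 for v in features.values() if v == v)}/28 populated):")
for name, value in features.items():
    print(f"  {name:13s} {value: .5g}")
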