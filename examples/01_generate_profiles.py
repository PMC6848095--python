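"""Generate the synthetic sagittal archetypes and locate their inflections.

Builds the five scoliotic subtype stand-ins plus the non-scoliotic mean,
prints each profile's detected kyphotic/lordotic split, and writes them as
landmark CSVs.  The split should reproduce the generator parameters
exactly: Group I types (2, 4) have short kyphotic segments with a
mid-thoracic inflection, Group II types (1, 3, 5) long kyphotic segments
with the inflection at the thoracolumbar junction.
"""

from pathlib import Path

from spinerod import find_inflection, generate_sagittal_profile
from spinerod.io import write_landmarks_csv
from spinerod.pipeline import DEFAULT_ARCHETYPES, GROUP_OF_TYPE

out = Path("example_output/profiles")
out.mkdir(parents=True, exist_ok=True)

for name, params in DEFAULT_ARCHETYPES.items():
    profile = generate_sagittal_profile(params, group_tag=GROUP_OF_TYPE[name])
    infl = find_inflection(profile)
    write_landmarks_csv(out / f"{name}.csv", profile)
    print(f"{name:13s} {GROUP_OF_TYPE[name]:12s} "
          f"kyphotic {infl.kyphotic_len:2d} / lordotic {infl.lordotic_len:2d} "
          f"inflection at level index {infl.inflection_level} "
          f"(0 = T1)")
print(f"\nLandmark CSVs written to {out}/")
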