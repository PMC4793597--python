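"""Run the whole study pipeline from one configuration.

Generates two phantom subjects (left + mirrored right limbs each), analyses
every limb in both views, and writes all artefacts — masks, densitograms,
false-colour PNGs, MAR and coordinate tables, summary and statistics — into
an output directory with a manifest.
"""

import json
from pathlib import Path

import ctoam

config = ctoam.RunConfig(
    output_dir="pipeline_out",
    phantom_subjects=("dog1", "dog2"),
    phantom_noise_sd=30.0,
    seed=1,
)
manifest = ctoam.run_pipeline(config)

print(f"status: {manifest['status']}, limbs analysed: {manifest['n_limbs']}")
print("artefacts:")
for artefact in manifest["artefacts"]:
    print("  ", artefact["path"])

mar = Path("pipeline_out/mar.csv").read_text().splitlines()
print("\nmar.csv (one row per limb and view):")
print("\n".join(mar))
# Re-running with the same config and seed reproduces these numbers exactly.
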