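"""Generate a synthetic raw-spectra table and average it per animal/tissue.

Emulates the acquisition design: 12 animals x 8 tissue types x 6 spots x 30
repetitions, each spectrum a smooth tissue mean curve plus a near-constant
animal shift, spot shift, a smooth per-animal deviation, and tiny
repetition noise.  A coarse 200-point wavelength grid keeps this quick.
"""

import spectrabench as sb

grid = sb.make_wavelength_grid(350.14, 649.98, 200)
model = sb.generate_ground_truth(sb.GroundTruthConfig(grid=grid), seed=1)
raw = sb.generate_raw_dataset(model, sb.RawDesign(), seed=1)
pre = sb.average_spectra(raw)

print(f"raw table: {len(raw)} spectra "
      f"({raw['Specimen'].nunique()} animals x {raw['Tissue'].nunique()} tissues "
      f"x {raw['Spot'].nunique()} spots x {raw['Repetition'].nunique()} reps)")
print(f"averaged table: {len(pre)} spectra, one per (animal, tissue)")
print("\nfirst rows (reflectance at the first three wavelengths):")
print(pre.iloc[:4, :5].to_string(index=False))
print("\nEach averaged row stands for one animal's tissue sample; reflectance "
      "is unitless intensity, typically 0-60 on this scale.")
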