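"""From image detections to per-litre abundances and biovolumes.

A net sample concentrates 100 L of seawater into a 3 L cod-end dilution
(45/50 fixed), of which Vi = 1 mL is imaged by confocal microscopy;
detections are converted back to the original-seawater scale via the
concentration factor Cf.  UVP5 colonies, imaged in situ in calibrated
volumes, are normalised directly.
"""

import pandas as pd

from diazoquant import (
    ImagingSample,
    SampleSpec,
    abundance_from_detections,
    biovolume_per_liter,
    concentration_factor,
    default_truth,
    ellipsoid_biovolume,
    simulate_imaging,
    uvp_concentration,
)

truth = default_truth()
spec = SampleSpec(sample_id="station_A", V_seawater=100.0, Vi=1e-3,
                  total_reads=1, seed=5)
sample = ImagingSample(sample_id="station_A", V_seawater=100.0, Vi=1e-3)

print(f"concentration factor Cf = {concentration_factor(sample):.1f} "
      f"(100 L net sample); Vi x Cf = {sample.Vi * concentration_factor(sample):.3f} L")

detections = simulate_imaging(truth, spec, labels=["Trichodesmium", "Richelia_Calothrix"])
for label, grp in detections.groupby("label"):
    a = abundance_from_detections(len(grp), sample)
    true_density = truth.taxon(label).density
    print(f"{label}: {len(grp)} detections -> {a:.3e} per L "
          f"(true density {true_density:.1e} per L)")

biovol = biovolume_per_liter(detections, sample, spheroid="prolate")
for label, v in biovol.items():
    print(f"{label}: {v:.3e} um^3/L biovolume (prolate ellipsoid)")

print(f"\na single 10 um sphere has biovolume {ellipsoid_biovolume(10, 10):.2f} um^3")
uvp = uvp_concentration(n_colonies=3, imaged_volume=40.0)
print(f"UVP5: 3 colonies in 40 L imaged in situ -> {uvp:.3f} colonies/L")
# Abundances divide counts by the effective seawater volume actually
# inspected (Vi x Cf for net samples, the calibrated volume for UVP5);
# biovolume sums the per-object ellipsoid volumes over the same volume.
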