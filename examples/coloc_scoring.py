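"""Score and classify inhibitory boutons in a synthetic confocal volume.

Generates a multichannel stack (Vgat + Syp-TdT + Syt1/2) with known class
labels, detects Vgat+ boutons as 3D local maxima, scores each bouton's
marker co-localization by regression R-squared inside a 1.5 x 1.5 x 1 um
VOI, and classifies them (GlyT2+ if R2 > 0.4, GlyT2- if R2 < 0.1).
"""

from synaptiq import (
    BoutonPopulation,
    VolumeSpec,
    analyze_volume,
    boutons_to_frame,
    generate_volume,
    match_boutons,
    truth_to_frame,
)

spec = VolumeSpec(shape_xy=(256, 256), seed=1)
pop = BoutonPopulation(count=40, p_glyt2=0.4, p_syt12=0.5)
stack, truth = generate_volume(spec, pop)
records = analyze_volume(stack)
frame = boutons_to_frame(records)

print(frame[["id", "x_um", "y_um", "z_um", "r2_syp_tdt", "glyt2_label"]]
      .head(10).to_string(index=False))

matched = match_boutons(records, truth_to_frame(truth))
correct = (matched["glyt2_label"] == matched["glyt2"].map(
    {True: "pos", False: "neg"})).mean()
print(f"\n{len(records)} boutons detected ({len(truth)} generated)")
print(f"GlyT2 classification accuracy vs ground truth: {correct:.1%}")
print("R2 near 1 means the marker intensity tracks Vgat voxel-for-voxel "
      "inside the bouton; near 0 means background only.")
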