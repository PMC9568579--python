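"""Extract the eight robust radiomics features from one synthetic lesion.

The extraction pipeline resamples to 1 mm isotropic voxels, discretizes
intensities with a fixed bin width of 10, and computes first-order, shape,
GLCM and GLDM statistics.
"""

from radhet import LesionGenParams, extract_features, generate_lesion

lesion = generate_lesion(
    LesionGenParams(radii_mm=(8.0, 6.0, 7.0), surface_noise=0.12,
                    intensity_mean=45.0, intensity_sd=18.0,
                    texture_corr_len_mm=2.0),
    rng=3,
)
fv = extract_features(lesion.image, lesion.mask, lesion.spacing, resample=False)

for name, value in fv.values.items():
    print(f"{name:45s} {value:12.4f}")

# VoxelVolume is in mm^3, diameters in mm; Sphericity is 1.0 for a perfect
# sphere; the GLDM/GLCM values summarize the texture of the discretized ROI.
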