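"""Generate a synthetic oligometastatic cohort and look at its lesions.

Each patient gets 2-5 lesions (perturbed ellipsoids with textured
intensity fields) whose generative parameters diverge within the patient
according to the heterogeneity level.
"""

from radhet import generate_cohort, preset_spec

spec = preset_spec("M-oligo", seed=7, heterogeneity_level=0.5)
cohort = generate_cohort(spec)

print(f"patients: {len(cohort)}")
for patient in cohort[:3]:
    sites = [lesion.site_label for lesion in patient.lesions]
    volumes = [int(lesion.mask.sum()) for lesion in patient.lesions]
    print(f"  {patient.patient_id}: {len(sites)} lesions, "
          f"sites={sites}, volumes(mm^3)={volumes}")

# Lesion counts per patient follow the oligometastatic definition (2-5
# visible tumors); mask voxel counts at 1 mm spacing are volumes in mm^3.
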