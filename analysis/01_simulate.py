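"""Generate the synthetic study cohorts and atlas used by every later stage.

Writes the discovery cohort (40 subjects, three condition pairs), a pair of
clinical cohorts (controls vs a group with attenuated regulation effects),
and a nearest-seed parcellation.  Text manifests go to results/simulation/;
NIfTI volumes (mask, atlas, example contrast maps) go to scratch/maps/.
"""

import json
from pathlib import Path

import numpy as np

from neurosig.synthetic import (
    CohortSpec,
    generate_clinical_cohorts,
    generate_cohort,
    generate_parcellation,
)
from neurosig.volume_core import write_map, write_mask, write_parcellation

SEED = 20260930
RESULTS = Path("results/simulation")
MAPS = Path("scratch/maps")


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    MAPS.mkdir(parents=True, exist_ok=True)

    spec = CohortSpec(seed=SEED)
    cohort = generate_cohort(spec)
    print(f"discovery cohort: {spec.n_subjects} subjects, "
          f"{cohort.mask.n_voxels} in-mask voxels, contrasts {spec.contrasts}")

    hc, cu = generate_clinical_cohorts(CohortSpec(seed=SEED + 1), attenuation=0.4)
    print("clinical cohorts: regulation amplitudes attenuated to 40% in group B")

    parc = generate_parcellation(spec.grid, n_regions=8, seed=SEED, mask=cohort.mask)
    print(f"parcellation: {len(parc.region_labels())} regions")

    write_mask(cohort.mask, MAPS / "mask.nii.gz")
    write_parcellation(parc, MAPS / "atlas.nii.gz", RESULTS / "atlas_labels.tsv")
    for pair in spec.contrasts:
        gt = cohort.ground_truth[pair]
        write_map(gt, cohort.mask, MAPS / f"truth_{pair}.nii.gz")
        sid = cohort.subject_ids[0]
        tgt, ctl = cohort.condition_pairs[pair][sid]
        write_map(tgt.values - ctl.values, cohort.mask, MAPS / f"{sid}_{pair}.nii.gz")

    manifest = {
        "seed": SEED,
        "n_subjects": spec.n_subjects,
        "grid": spec.grid.dims,
        "n_voxels": cohort.mask.n_voxels,
        "contrasts": spec.contrasts,
        "amplitudes": spec.amplitudes,
        "noise_sd": spec.noise_sd,
        "smooth_noise_sd": spec.smooth_noise_sd,
        "component_norms": {
            k: float(np.linalg.norm(v)) for k, v in cohort.components.items()
        },
        "clinical_attenuation": 0.4,
    }
    (RESULTS / "ground_truth_manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n"
    )
    print(f"wrote manifest to {RESULTS/'ground_truth_manifest.json'}")


if __name__ == "__main__":
    main()
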