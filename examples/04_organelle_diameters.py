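"""Recover organelle diameters from a synthetic organelle channel.

Endosome- and lysosome-like compartments are rendered as PSF-blurred spheres;
the default processing chain (Richardson–Lucy deconvolution, then 2 px
lateral smoothing) followed by Otsu segmentation recovers their sizes via the
equivalent-sphere diameter.
"""

import numpy as np

from qdepth import (
    OrganelleSpec,
    PreprocessParams,
    SceneSpec,
    VoxelSpacing,
    deconvolve_ml,
    equivalent_diameter,
    label_objects,
    otsu_threshold,
    render_scene,
    smooth_lateral,
)

spacing = VoxelSpacing()
params = PreprocessParams()

for name, true_d in (("endosome-like", 0.6), ("lysosome-like", 0.9)):
    spheres = [OrganelleSpec(true_d, (4.0, 2.5 + 3.0 * r, 2.0 + 3.0 * c))
               for r in range(2) for c in range(3)]
    spec = SceneSpec(shape=(48, 160, 160), spacing=spacing, membrane_depth_um=3.0,
                     organelles=spheres, seed=int(true_d * 100))
    scene = render_scene(spec)

    work = deconvolve_ml(scene.organelles, params.psf_sigma_um, params.deconv_iterations)
    work = smooth_lateral(work, params.qd_smooth_sigma_px)
    objects, _ = label_objects(work, otsu_threshold(work), spacing)
    diameters = [equivalent_diameter(o, spacing)
                 for o in objects if o.voxel_count > 50]
    print(f"{name:14s} true {true_d:.1f} µm -> measured "
          f"{np.mean(diameters):.2f} ± {np.std(diameters):.2f} µm (n = {len(diameters)})")

# The residual ~0.05-0.1 µm inflation is the footprint of the point-spread
# function that 40 deconvolution iterations do not fully remove.
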