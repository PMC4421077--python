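"""Compare denoisers on a noisy vessel phantom by PSNR.

A clean bar phantom is corrupted with Gaussian noise (sigma 20) and
restored with a Gaussian filter, a median filter, Perona-Malik diffusion
and directional anisotropic diffusion (DAD).  PSNR against the clean
original is the figure of merit (higher is better).  Both diffusions
improve on the noisy input while limiting how far the image drifts from
the original; note that on a smooth Gaussian-profile phantom aggressive
linear smoothing also scores a high PSNR, since there are no sharp edges
to destroy — the diffusions' selling point, edge preservation, shows in
the step-edge gradient report printed last.
"""

import vesselkit as vk

clean = vk.make_bar_phantom(vk.VesselPhantomSpec(radius=4.0), 96, 96)
noisy = vk.add_gaussian_noise(clean, vk.NoiseSpec(sigma=20.0, seed=1))

restored = {
    "noisy input": noisy,
    "Gaussian 9x9, sigma 2": vk.gaussian_baseline(noisy, 2.0, 9),
    "median 5x5": vk.median_baseline(noisy, 5),
    "PM (k=7, dt=0.15, 13 it)": vk.pm_diffuse(noisy, vk.PMParams(k=7.0, dt=0.15, n_iter=13)),
    "DAD (k=7, a=0.5, b=0.05, 50 it)": vk.dad_diffuse(
        noisy, vk.DADParams(k=7.0, alpha=0.5, beta=0.05, dt=0.05, n_iter=50, sigma_reg=0.8)),
}
for name, img in restored.items():
    print(f"{name:32s} PSNR = {vk.psnr(clean, img):7.4f} dB   MSE = {vk.mse(clean, img):9.4f}")

# edge preservation: a 100-high step smoothed 100 iterations
import numpy as np

step = np.zeros((32, 64))
step[:, 32:] = 100.0
for name, out in (
    ("PM k=3 (edge-stopping)", vk.pm_diffuse(step, vk.PMParams(k=3.0, dt=0.15, n_iter=100))),
    ("heat equation (k -> inf)", vk.pm_diffuse(step, vk.PMParams(k=1e12, dt=0.15, n_iter=100))),
):
    g = np.abs(np.diff(out, axis=1)).max()
    print(f"step edge after {name:26s}: max gradient {g:6.2f} (initially 100)")
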