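# meddiffusion

Conditional denoising diffusion probabilistic models (cDDPM) for medical
image restoration, implemented from first principles in NumPy: the full
probabilistic machinery — forward noising chain, closed-form marginal,
forward posterior, variational-bound terms, discretized Gaussian decoder,
simplified noise-matching objective, ancestral sampling — plus three
conditional image-to-image pipelines (MRI-style super-resolution, X-ray-style
denoising, MRI-style inpainting), exercisable end to end at desk scale on
synthetic anatomy-like phantoms.

The trainable noise predictor is a conditional U-Net (group normalization,
SiLU, sinusoidal time embedding, condition image concatenated at the input)
built on a small reverse-mode autodiff engine included in the package, so no
deep-learning framework is required.

## Layout

| Module | Contents |
| --- | --- |
| `meddiffusion.schedules` | `NoiseSchedule`, linear beta schedule, posterior coefficients |
| `meddiffusion.diffusion` | `q_sample` (+ stepwise oracle), forward posterior, reverse step, ancestral sampling loop |
| `meddiffusion.losses` | simplified loss, Gaussian KL, per-term variational bound, discretized decoder likelihood |
| `meddiffusion.nn` | autodiff engine, reference U-Net, Adam training loop, checkpoints |
| `meddiffusion.conditioning` | SR / noise / inpainting degradations, patient-wise normalization |
| `meddiffusion.phantoms` | synthetic phantom generator (three styles), task datasets with 80/10/10 splits |
| `meddiffusion.metrics` | accutance (mean Sobel gradient), Dice, PSNR |
| `meddiffusion.io_utils`, `config`, `experiment`, `cli` | PNG/NIfTI I/O, YAML configs, experiment orchestration, CLI |

## CLI

```bash
# generate phantoms
meddiffusion synth --style prostate_t2 --n 16 --size 64 --seed 7 --out phantoms/

# full toy experiment (train + sample + evaluate) on a task
cat > cfg.yaml <<EOF
seed: 7
out_dir: runs/denoise_toy
task: {name: denoise}
EOF
meddiffusion run --config cfg.yaml --toy

# train / sample / evaluate individually
meddiffusion train --config cfg.yaml --toy --out ckpt.npz
meddiffusion sample --config cfg.yaml --toy --checkpoint ckpt.npz \
    --condition runs/denoise_toy/samples/0000_condition.png --seed 1 --out out.png
meddiffusion evaluate --pred preds/ --ref refs/ --out report.json
```

Default hyperparameters follow the reference setup (T=2000, linear β from
1e-4 to 0.02, σ²ₜ=βₜ, 128×128, lr 1e-4, 2×10⁵ iterations); `--toy` switches
to the CPU-scale profile (16×16, T=200, ~2k iterations) used by the tests.

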