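"""Unconditional backbone generation with latent-space diffusion.

Trains the miniature auto-encoder, then a small denoising-diffusion model
over the quantized latent arrays, samples a handful of new latent arrays
from pure noise, snaps them onto the codebook and decodes them into 3-D
backbones.  The mutual TM-score between samples measures the diversity of
the generated set (lower = more diverse; 1.0 = identical folds), and the
secondary-structure fractions show what the generator learned to produce.
"""

import numpy as np

from vqfold import (AutoencoderConfig, DiffusionConfig, SamplerConfig,
                    ToyDatasetConfig, composition_report, generate_backbones,
                    make_toy_dataset, mutual_tm, quantize, train_autoencoder,
                    train_diffusion)

data = make_toy_dataset(ToyDatasetConfig(n_structures=8, length_range=(40, 40),
                                         seed=3))
ae_cfg = AutoencoderConfig(n_codes=32, steps_phase1=600, steps_phase2=0, seed=0)
print("training auto-encoder...")
ae, _ = train_autoencoder(data, ae_cfg)

latents = [quantize(ae.encode(s), ae.codebook.data)[1].values
           for _, s in data]
# a short schedule with time-compressed betas keeps the same total noise
diff_cfg = DiffusionConfig(T=50, beta_1=8e-4, beta_T=0.16, steps=600, seed=1)
print("training latent diffusion model...")
model, _ = train_diffusion(latents, diff_cfg)

ens = generate_backbones(model, ae, SamplerConfig(n_samples=4, length=40,
                                                  seed=7))
_, median_tm = mutual_tm(ens)
comp = composition_report(ens)
print(f"sampled {len(ens)} backbones of length {ens.n_residues}")
print(f"median mutual TM-score: {median_tm:.2f}")
print("secondary-structure fractions:",
      {k: round(v, 2) for k, v in comp.ss_fractions.items()})
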