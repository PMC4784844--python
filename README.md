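# hpcfill

A hierarchical predictive-coding (HPC) model of perceptual filling-in at
the retinal blind spot.

A three-level predictive-estimator network (LGN -> V1 -> V2) is trained on
naturalistic image patches: nine level-1 modules (64 neurons each, one
shared basis) tile a 30x30 input into overlapping 12x12 sub-patches, and a
single level-2 module (169 neurons) predicts the concatenated level-1
state. Inference minimizes a coding length combining masked bottom-up
reconstruction error, top-down consistency error, a kurtotic sparse prior
on responses and a Gaussian prior on weights; learning is a Hebbian-like
batch rule with per-neuron gain homeostasis. A blind spot is emulated by
zeroing the feed-forward error pathway over the central 8x8 region of a
pre-trained network. Bar-stimulus experiments then reproduce the signature
phenomena: supra-additive (AND-gate) responses when a bar stimulates both
flanks of the blind spot, abrupt response elevation as a shifting bar
crosses it, perceptual completion of the bar in the reconstructed
"perceptual image", and completion that fades with vertical misalignment
of the flanking segments.

## Layout

| module | role |
| --- | --- |
| `hpcfill.synthetic_data` | surrogate natural images (1/f noise + composited segment textures) and the bar-stimulus batteries |
| `hpcfill.preprocessing` | DC removal, whitening/lowpass filter `W(f) = f exp(-(f/f0)^4)`, patch sampling, 9-window tiling |
| `hpcfill.model_core` | coding length, sparse prior, joint state dynamics, steady-state relaxation, perceptual images |
| `hpcfill.training` | level-1/level-2 basis learning, gain adaptation, receptive-field metrics |
| `hpcfill.blind_spot` | blind-spot mask construction and feed-forward lesioning |
| `hpcfill.experiments` | stimulus batteries, response normalization, AND-gate test, shifting-bar profiles, misalignment completion curve |
| `hpcfill.cli_io` | YAML/JSON config, HDF5 persistence, `hpcfill` CLI |

## CLI

```bash
hpcfill gen-images --out runs/images --count 6 --size 256 --seed 0
hpcfill train --seed 1 --out runs/net.h5            # surrogates generated on the fly
hpcfill lesion --archive runs/net.h5 --out runs/bs.h5
hpcfill run-shifting-bar --archive runs/net.h5 --bs-archive runs/bs.h5 --out runs/exp
hpcfill run-nonlinearity --bs-archive runs/bs.h5 --out runs/exp
hpcfill run-misalignment --bs-archive runs/bs.h5 --out runs/exp
hpcfill report --run-dir runs/exp --out runs/exp/summary.json
```

All commands accept `--config config.yaml`; omitted fields default to the
study's printed parameter values (k1=1, k2=3, sigma^2=3, sigma^2_td=10,
alpha=0.05/0.1, lambda=0.0025, sigma^2_goal=0.05, gamma=0.02, f0=200
cycles/image). Weights and masks are persisted in one HDF5 archive;
responses go to CSV, summaries to JSON, image previews to PNG.

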