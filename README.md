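# pvrnn-agency

A multimodal predictive-coding variational recurrent network with
per-layer *meta-prior* weighting of the KL (complexity) term, multiple
timescale leaky-integrator dynamics, a convolutional vision latent
codec, and shifting-window *error-regression* (ER) inference — together
with a synthetic visuo-proprioceptive data generator, so the two
desk-scale experiments (modality-specific complexity regulation, and a
global meta-prior sweep modulating "strength of agency") can be run
end to end on one CPU.

Everything runs on NumPy: the package ships a small reverse-mode
autodiff engine (`pvrnn_agency.autodiff`) whose gradients are validated
against central finite differences in the test suite, so no deep
learning framework is required.

## Layout

| module | what it does |
|---|---|
| `synthetic_data` | 3-primitive probabilistic state machine (A→{B,C} 50/50, B/C→A), smooth 16-joint trajectories in [−1,1], stick-figure frames with illumination noise; CSV/PNG/manifest IO |
| `pvrnn_core` | layer math: leaky integration, sequential prior, adaptive-variable posterior, reparameterization, closed-form diagonal-Gaussian KL |
| `network` | associative + proprioception + vision modules (slow/fast layers), same-time-step top-down wiring, meta-prior-weighted cost |
| `vision_codec` | stride-1 conv encoder/decoder (64→32→16→1 spatial chain, CoordConv), latent bridge to the RNN's vision latent |
| `training` | offline BPTT with Adam over weights *and* per-sequence adaptive variables |
| `error_regression` | rolling ER window: frozen weights, per-slot adaptive variables re-optimized every sensory step; look-ahead rollouts; interaction metrics |
| `experiments` | experiment runners and reports |
| `cli` | `pvrnn-agency` command-line interface |

## CLI

```sh
pvrnn-agency gen-data --out scratch/data --n-sequences 6 --n-segments 4 \
    --segment-len 25 --image-size 16 --seed 3
pvrnn-agency codec train --data scratch/data --out scratch/codec.h5 \
    --image-size 16 --latent-dim 8 --epochs 20
pvrnn-agency train --data scratch/data --codec-checkpoint scratch/codec.h5 \
    --out scratch/run --epochs 500
pvrnn-agency interact --model-checkpoint scratch/run/model.h5 \
    --codec-checkpoint scratch/codec.h5 --data scratch/data \
    --out scratch/er --meta-setting W3
pvrnn-agency exp1 --out scratch/experiments   # modality-specific meta-priors
pvrnn-agency exp2 --out scratch/experiments   # five-setting agency sweep
```

Defaults reproduce the reference protocol (30 sequences × 8 segments ×
50 steps = 400 steps, 64×64 frames, 20-dim vision latent); the desk-scale
settings shown above are what the tests use.

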