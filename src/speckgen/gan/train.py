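"""Training loop: alternating Adam updates with non-saturating losses,
paired geometric augmentation, periodic FID validation and best-checkpoint
retention.  Fully seeded: a fixed config seed reproduces the loss log
bit for bit on one machine."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .. import io as sgio
from ..metrics import DeskEmbedder, embed_images, fid, gaussian_stats
from .autodiff import Tensor
from .config import GanConfig
from .losses import loss_discriminator, loss_generator
from .models import Discriminator, Generator
from .optim import Adam

__all__ = [
    "load_dataset",
    "augment_pair",
    "train_gan",
    "save_checkpoint",
    "load_checkpoint",
    "generate_images",
]


def load_dataset(data_dir: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load (phantom_*.png, mask_*.png) pairs from a directory.

    Returns images (n, h, w) in [0, 1] and integer masks (n, h, w).
    """
    data_dir = Path(data_dir)
    image_paths = sorted(data_dir.glob("phantom_*.png"))
    if not image_paths:
        raise ValueError(f"no phantom_*.png images found in {data_dir}")
    images, masks = [], []
    for img_path in image_paths:
        mask_path = data_dir / img_path.name.replace("phantom_", "mask_")
        if not mask_path.exists():
            raise ValueError(f"missing mask for {img_path.name}")
        img = sgio.read_image(img_path)
        msk = sgio.read_mask(mask_path)
        if img.shape != msk.shape:
            raise ValueError(f"shape mismatch for pair {img_path.name}")
        images.append(img)
        masks.append(msk)
    return np.stack(images), np.stack(masks)


def augment_pair(
    image: np.ndarray, mask: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random rotation plus horizontal/vertical flips to an
    image/mask pair; the mask is resampled nearest-neighbor so its label set
    is preserved."""
    rng = np.random.default_rng(seed)
    angle = float(rng.uniform(0.0, 360.0))
    flip_h = bool(rng.integers(0, 2))
    flip_v = bool(rng.integers(0, 2))
    img = ndimage.rotate(image, angle, reshape=False, order=1, mode="constant")
    msk = ndimage.rotate(mask, angle, reshape=False, order=0, mode="constant", cval=2)
    if flip_h:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if flip_v:
        img, msk = img[::-1, :], msk[::-1, :]
    return np.clip(img, 0.0, 1.0).copy(), msk.copy()


def save_checkpoint(path: str | Path, gen: Generator, disc: Discriminator | None,
                    cfg: GanConfig, meta: dict | None = None) -> None:
    arrays = {f"gen.{k}": v for k, v in gen.state_dict().items()}
    if disc is not None:
        arrays.update({f"disc.{k}": v for k, v in disc.state_dict().items()})
    arrays["__config__"] = np.frombuffer(
        json.dumps({"config": cfg.to_dict(), "meta": meta or {}}).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[Generator, Discriminator | None, dict]:
    with np.load(path) as data:
        payload = json.loads(bytes(data["__config__"]).decode())
        cfg = GanConfig.from_dict(payload["config"])
        gen = Generator(cfg)
        gen.load_state_dict(
            {k[4:]: data[k] for k in data.files if k.startswith("gen.")}
        )
        disc_keys = [k for k in data.files if k.startswith("disc.")]
        disc = None
        if disc_keys:
            disc = Discriminator(cfg)
            disc.load_state_dict({k[5:]: data[k] for k in disc_keys})
    return gen, disc, payload["meta"]


def _validation_fid(
    gen: Generator,
    images: np.ndarray,
    masks: np.ndarray,
    rng: np.random.Generator,
    embedder: "DeskEmbedder",
    n_images: int,
) -> float:
    gen.eval()
    fakes = []
    for i in range(n_images):
        z = rng.normal(size=(1, gen.cfg.z_dim))
        out = gen(z, masks[i % len(masks)][None], speckle_rng=rng)
        fakes.append(out.data[0, 0])
    gen.train()
    real_feats = embed_images(list(images), embedder)
    fake_feats = embed_images(fakes, embedder)
    return fid(gaussian_stats(real_feats), gaussian_stats(fake_feats))


def train_gan(
    data_dir: str | Path,
    cfg: GanConfig,
    out_dir: str | Path,
    embedder=None,
) -> dict:
    """Train on a directory of (phantom, mask) pairs.

    Writes ``log.csv`` (step, epoch, loss_D, loss_G, fid, d_0..d_{S-1}),
    ``best.npz`` (lowest validation FID) and ``run.json`` (config + seed
    record) into ``out_dir``.  Returns a summary dict with the loss history
    and the best FID.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, masks = load_dataset(data_dir)
    if len(images) < 2:
        raise ValueError("need at least 2 training pairs")
    if images.shape[1] != cfg.image_size:
        raise ValueError(
            f"dataset images are {images.shape[1]}px but config expects "
            f"{cfg.image_size}px"
        )
    embedder = embedder or DeskEmbedder()

    rng = np.random.default_rng(cfg.seed)
    gen = Generator(cfg)
    disc = Discriminator(cfg)
    opt_g = Adam(gen.parameters(), cfg.lr_init, cfg.adam_beta1, cfg.adam_beta2,
                 cfg.adam_eps)
    opt_d = Adam(disc.parameters(), cfg.lr_init, cfg.adam_beta1, cfg.adam_beta2,
                 cfg.adam_eps)

    n = len(images)
    steps_per_epoch = max(n // cfg.batch_size, 1)
    decay = (cfg.lr_final / cfg.lr_init) ** (1.0 / max(len(cfg.lr_milestones), 1))

    def sample_batch(idx):
        batch_img, batch_msk = [], []
        for i in idx:
            im, mk = augment_pair(images[i], masks[i], int(rng.integers(1 << 31)))
            batch_img.append(im)
            batch_msk.append(mk)
        return np.stack(batch_img)[:, None], np.stack(batch_msk)

    # optional discriminator warm-up: D-only updates against early fakes
    for _ in range(cfg.disc_warmup_steps):
        idx = rng.permutation(n)[: cfg.batch_size]
        x_real, m_real = sample_batch(idx)
        z = rng.normal(size=(len(idx), cfg.z_dim))
        fake = gen(z, m_real, speckle_rng=rng)
        l_d = loss_discriminator(
            disc(x_real, m_real), disc(Tensor(fake.data.copy()), m_real)
        )
        opt_d.zero_grad()
        opt_g.zero_grad()
        l_d.backward()
        opt_d.step()

    log_rows: list[dict] = []
    best_fid = np.inf
    step = 0
    for epoch in range(cfg.epochs):
        n_past = sum(1 for m in cfg.lr_milestones if epoch >= m)
        lr = cfg.lr_init * decay**n_past
        opt_g.lr = lr
        opt_d.lr = lr * cfg.lr_disc_scale

        order = rng.permutation(n)
        for b in range(steps_per_epoch):
            idx = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            if idx.size == 0:
                idx = order[: cfg.batch_size]
            x_real, m_real = sample_batch(idx)

            # --- discriminator update (generator output detached) ---
            z = rng.normal(size=(len(idx), cfg.z_dim))
            fake = gen(z, m_real, speckle_rng=rng)
            d_real = disc(x_real, m_real)
            d_fake = disc(Tensor(fake.data.copy()), m_real)
            l_d = loss_discriminator(d_real, d_fake)
            opt_d.zero_grad()
            opt_g.zero_grad()
            l_d.backward()
            opt_d.step()

            # --- generator update (reuses the live fake graph) ---
            d_fake = disc(fake, m_real)
            l_g = loss_generator(d_fake)
            opt_g.zero_grad()
            opt_d.zero_grad()
            l_g.backward()
            opt_g.step()

            step += 1
            row = {
                "step": step,
                "epoch": epoch,
                "loss_D": float(l_d.data),
                "loss_G": float(l_g.data),
                "fid": "",
            }
            for si, d_val in enumerate(gen.window_sizes()):
                row[f"d_{si}"] = d_val
            log_rows.append(row)

        if (epoch + 1) % cfg.fid_interval == 0 or epoch == cfg.epochs - 1:
            n_fid = cfg.fid_images or n
            val = _validation_fid(gen, images, masks, rng, embedder, n_fid)
            log_rows[-1]["fid"] = val
            if val < best_fid:
                best_fid = val
                save_checkpoint(out_dir / "best.npz", gen, disc, cfg,
                                meta={"epoch": epoch, "fid": val})

    fieldnames = list(log_rows[0].keys())
    with open(out_dir / "log.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(log_rows)
    with open(out_dir / "run.json", "w") as fh:
        json.dump({"config": cfg.to_dict(), "best_fid": best_fid,
                   "n_pairs": n, "steps": step}, fh, indent=2)
    return {"log": log_rows, "best_fid": best_fid, "out_dir": str(out_dir)}


def generate_images(
    checkpoint: str | Path,
    masks: np.ndarray,
    n: int,
    seed: int,
    out_dir: str | Path | None = None,
) -> np.ndarray:
    """Sample ``n`` images from a trained generator, cycling over the given
    masks; optionally write them (plus the masks used) as PNG pairs."""
    gen, _, _ = load_checkpoint(checkpoint)
    gen.eval()
    rng = np.random.default_rng(seed)
    outs = []
    for i in range(n):
        z = rng.normal(size=(1, gen.cfg.z_dim))
        mask = masks[i % len(masks)]
        out = gen(z, mask[None], speckle_rng=rng)
        outs.append(out.data[0, 0])
    result = np.stack(outs)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, img in enumerate(result):
            sgio.write_image(img, out_dir / f"gen_{i:04d}.png")
            sgio.write_mask(masks[i % len(masks)], out_dir / f"genmask_{i:04d}.png")
    return result
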