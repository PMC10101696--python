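"""Exact values and brute-force oracles for every loss term."""

import numpy as np
import pytest

from ccaae.autodiff import Tensor
from ccaae.losses import (
    LossWeights,
    adversarial_losses,
    anchor_loss,
    classifier_loss,
    contrastive_loss,
    cycle_consistency_loss,
    mine_hard_triplets,
    mmd_loss,
    reconstruction_loss,
    rowwise_distance,
)
from ccaae.networks import build_networks
from ccaae.nn import Linear


# ---------------------------------------------------------------- test rigs
class _IdentityMap:
    """Stand-in network computing the identity (or a fixed numpy map)."""

    n_in = None

    def __init__(self, fn=None):
        self.fn = fn or (lambda x: x)

    def __call__(self, x):
        return self.fn(x)

    def parameters(self):
        return []


class _NetsStub:
    """Duck-typed CoupledNets with pluggable per-modality maps."""

    def __init__(self, enc_rna=None, enc_atac=None, dec_rna=None, dec_atac=None):
        self._enc = {"rna": _IdentityMap(enc_rna), "atac": _IdentityMap(enc_atac)}
        self._dec = {"rna": _IdentityMap(dec_rna), "atac": _IdentityMap(dec_atac)}

    def encoder(self, modality):
        return self._enc[modality]

    def decoder(self, modality):
        return self._dec[modality]

    def encode_t(self, x, modality):
        return self._enc[modality](x)


def _weights_invalid():
    with pytest.raises(ValueError):
        LossWeights(w_recon=-1.0)
    with pytest.raises(ValueError):
        LossWeights(margin_alpha=0.0)
    with pytest.raises(ValueError):
        LossWeights(distance="cosine")


# -------------------------------------------------------------- reconstruction
def test_reconstruction_identity_codec_is_zero(rng):
    nets = _NetsStub()
    x = Tensor(rng.normal(size=(5, 3)))
    assert float(reconstruction_loss(nets, x, x).data) == 0.0


def test_reconstruction_arithmetic():
    # rna cell (1,2,2) reconstructed as (0,0,0): (1+4+4)/3 = 3; atac term 0
    nets = _NetsStub(dec_rna=lambda z: z * 0.0)
    xr = Tensor([[1.0, 2.0, 2.0]])
    xa = Tensor([[7.0]])
    assert float(reconstruction_loss(nets, xr, xa).data) == pytest.approx(3.0)


def test_reconstruction_batch_mean_oracle(rng):
    nets = build_networks(4, 5, latent_dim=3, hidden=(6,), disc_hidden=(4,), seed=0)
    xr, xa = rng.normal(size=(2, 4)), rng.normal(size=(2, 5))
    batched = float(reconstruction_loss(nets, Tensor(xr), Tensor(xa)).data)
    singles = [
        float(reconstruction_loss(nets, Tensor(xr[i : i + 1]), Tensor(xa[i : i + 1])).data)
        for i in range(2)
    ]
    assert batched == pytest.approx(np.mean(singles))


def test_empty_batch_errors():
    nets = _NetsStub()
    with pytest.raises(ValueError, match="empty"):
        reconstruction_loss(nets, Tensor(np.empty((0, 3))), Tensor(np.ones((1, 3))))


# ----------------------------------------------------------------- adversarial
def _zero_disc_nets():
    """Networks whose discriminator outputs exactly 0.5 everywhere."""
    nets = build_networks(3, 3, latent_dim=2, hidden=(4,), disc_hidden=(4,), seed=0)
    last = nets.discriminator.net.layers[-1]
    last.W.data[:] = 0.0
    last.b.data[:] = 0.0
    return nets


def test_adversarial_half_is_ln2(rng):
    nets = _zero_disc_nets()
    zr, za = Tensor(rng.normal(size=(4, 2))), Tensor(rng.normal(size=(3, 2)))
    disc, gen = adversarial_losses(nets, zr, za)
    assert float(disc.data) == pytest.approx(np.log(2.0))
    assert float(gen.data) == pytest.approx(np.log(2.0))


def test_adversarial_confident_disc_limits(rng):
    nets = _zero_disc_nets()
    # logits = 20 * first latent coordinate: rna at +1, atac at -1
    nets.discriminator.net.layers[0].W.data[:] = 0.0
    nets.discriminator.net.layers[0].b.data[:] = 1.0
    last = nets.discriminator.net.layers[-1]
    last.W.data[:, 0] = 5.0  # all-positive hidden -> logit 20
    zr = Tensor(np.ones((3, 2)))
    za = Tensor(-np.ones((3, 2)))
    # make atac logits strongly negative instead: use sign-sensitive first layer
    nets.discriminator.net.layers[0].W.data[:] = np.full((2, 4), 10.0)
    nets.discriminator.net.layers[0].b.data[:] = 0.0
    disc, gen = adversarial_losses(nets, zr, za)
    assert float(disc.data) < 1e-3
    assert float(gen.data) > 5.0


def test_adversarial_oracle_formula(rng):
    nets = build_networks(3, 3, latent_dim=4, hidden=(5,), disc_hidden=(6,), seed=3)
    zr, za = rng.normal(size=(4, 4)), rng.normal(size=(4, 4))
    disc, gen = adversarial_losses(nets, Tensor(zr), Tensor(za))
    with np.errstate(over="ignore"):
        pr = 1 / (1 + np.exp(-nets.discriminator.logits(Tensor(zr)).data.ravel()))
        pa = 1 / (1 + np.exp(-nets.discriminator.logits(Tensor(za)).data.ravel()))
    expected_disc = np.mean(np.concatenate([-np.log(pr), -np.log(1 - pa)]))
    expected_gen = np.mean(np.concatenate([-np.log(1 - pr), -np.log(pa)]))
    assert float(disc.data) == pytest.approx(expected_disc)
    assert float(gen.data) == pytest.approx(expected_gen)


def test_adversarial_nonfinite_rejected():
    nets = _zero_disc_nets()
    bad = Tensor(np.array([[np.inf, 0.0]]))
    with pytest.raises(ValueError, match="non-finite"):
        adversarial_losses(nets, bad, Tensor(np.zeros((2, 2))))


# --------------------------------------------------------------------- cycle
def test_cycle_identity_maps_zero(rng):
    nets = _NetsStub()
    x = Tensor(rng.normal(size=(4, 3)))
    assert float(cycle_consistency_loss(nets, x, x).data) == 0.0


def test_cycle_arithmetic_worked_example():
    # rna latent z=(1,0); Di(z)=(2,0); Ei((2,0))=(1,1): d = ((0)^2+(1)^2)/2 = 0.5
    # atac term: Ei(xa=(0,0)) = (0,1) -> Dj identity -> Ej identity -> distance 0
    nets = _NetsStub(
        enc_rna=lambda x: x,
        dec_atac=lambda z: z * 2.0,
        enc_atac=lambda y: y * 0.5 + Tensor([0.0, 1.0]),
        dec_rna=lambda z: z,
    )
    xr = Tensor([[1.0, 0.0]])
    xa = Tensor([[0.0, 0.0]])
    assert float(cycle_consistency_loss(nets, xr, xa).data) == pytest.approx(0.5)


def test_cycle_oracle_composition(rng):
    nets = build_networks(4, 4, latent_dim=3, hidden=(5,), disc_hidden=(4,), seed=1)
    xr, xa = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
    got = float(cycle_consistency_loss(nets, Tensor(xr), Tensor(xa)).data)

    def step(x, modality, other):
        z = nets.encode_t(Tensor(x), modality).data
        back = nets.encoder(other)(nets.decoder(other)(Tensor(z))).data
        return np.mean(np.sum((z - back) ** 2, axis=1) / z.shape[1])

    expected = step(xr, "rna", "atac") + step(xa, "atac", "rna")
    assert got == pytest.approx(expected)


# ----------------------------------------------------------------- contrastive
def test_mining_forced_cases():
    pts = np.array([[0.0], [1.0], [10.0]])
    triples = mine_hard_triplets(pts, ["A", "A", "B"])
    assert (0, 1, 2) in triples  # anchor 0: only candidates
    pts = np.array([[0.0], [1.0], [2.0], [10.0], [11.0]])
    triples = dict(
        (a, (p, n)) for a, p, n in mine_hard_triplets(pts, ["A", "A", "A", "B", "B"])
    )
    assert triples[0] == (2, 3)  # farthest same-label, nearest other-label


def test_mining_single_label_errors():
    with pytest.raises(ValueError, match="two labels"):
        mine_hard_triplets(np.zeros((3, 1)), ["A", "A", "A"])


def brute_force_triplets(coords, labels):
    labels = np.asarray(labels)
    out = []
    for a in range(len(coords)):
        best_p, best_pd = None, -np.inf
        best_n, best_nd = None, np.inf
        for j in range(len(coords)):
            d = np.mean((coords[a] - coords[j]) ** 2)
            if j != a and labels[j] == labels[a] and d > best_pd:
                best_p, best_pd = j, d
            if labels[j] != labels[a] and d < best_nd:
                best_n, best_nd = j, d
        if best_p is not None and best_n is not None:
            out.append((a, best_p, best_n))
    return out


def test_mining_matches_bruteforce(rng):
    coords = rng.normal(size=(40, 3))
    labels = rng.choice(list("XYZ"), size=40)
    assert mine_hard_triplets(coords, labels) == brute_force_triplets(coords, labels)


def test_mining_permutation_invariant(rng):
    coords = rng.normal(size=(20, 2))
    labels = rng.choice(list("AB"), size=20)
    perm = rng.permutation(20)
    orig = mine_hard_triplets(coords, labels)
    permuted = mine_hard_triplets(coords[perm], labels[perm])
    # row i of the permuted pool is original row perm[i]
    mapped = sorted((int(perm[a]), int(perm[p]), int(perm[n])) for a, p, n in permuted)
    assert mapped == sorted((a, p, n) for a, p, n in orig)


def test_contrastive_hinge_values():
    # anchor at 0 with d(a,p)=1, d(a,n)=5, alpha=1 -> hinge max(0, 1-5+1) = 0
    pool = np.array([[0.0], [1.0], [np.sqrt(5.0)]])
    val = float(contrastive_loss(pool, ["A", "A", "B"], margin_alpha=1.0).data)
    per_anchor = [max(0.0, 1 - 5 + 1), max(0.0, 1 - (np.sqrt(5) - 1) ** 2 + 1)]
    assert val == pytest.approx(np.mean(per_anchor))
    # anchor at 0 with d(a,p)=3, d(a,n)=1, alpha=1 -> hinge 3
    pool = np.array([[0.0], [np.sqrt(3.0)], [1.0]])
    val = float(contrastive_loss(pool, ["A", "A", "B"], margin_alpha=1.0).data)
    per_anchor = [3 - 1 + 1, 3 - (np.sqrt(3) - 1) ** 2 + 1]
    assert val == pytest.approx(np.mean(per_anchor))


def test_contrastive_zero_iff_margin_satisfied(rng):
    # two tight, far-apart clusters: every triplet satisfies the margin
    a = rng.normal(size=(6, 2)) * 0.01
    b = rng.normal(size=(6, 2)) * 0.01 + 100.0
    pool = np.vstack([a, b])
    labels = ["A"] * 6 + ["B"] * 6
    assert float(contrastive_loss(pool, labels, margin_alpha=1.0).data) == 0.0
    # collapse the clusters onto each other: loss strictly positive
    pool2 = np.vstack([a, a])
    assert float(contrastive_loss(pool2, labels, margin_alpha=1.0).data) > 0.0


def test_contrastive_matches_bruteforce(rng):
    pool = rng.normal(size=(12, 3))
    labels = rng.choice(list("AB"), size=12)
    alpha = 0.7
    got = float(contrastive_loss(pool, labels, alpha).data)
    hinges = []
    for a, p, n in brute_force_triplets(pool, labels):
        dp = np.mean((pool[a] - pool[p]) ** 2)
        dn = np.mean((pool[a] - pool[n]) ** 2)
        hinges.append(max(0.0, dp - dn + alpha))
    assert got == pytest.approx(np.mean(hinges))


# ------------------------------------------------------------------ classifier
def test_classifier_uniform_is_ln_m(rng):
    nets = build_networks(3, 3, latent_dim=4, hidden=(4,), disc_hidden=(4,),
                          classes=["a", "b", "c", "d"], seed=0)
    nets.classifier.lin.W.data[:] = 0.0
    nets.classifier.lin.b.data[:] = 0.0
    z = rng.normal(size=(5, 4))
    val = float(classifier_loss(nets, z, ["a", "b", "c", "d", "a"]).data)
    assert val == pytest.approx(np.log(4.0))


def test_classifier_confident_near_zero():
    nets = build_networks(3, 3, latent_dim=2, hidden=(4,), disc_hidden=(4,),
                          classes=["a", "b"], seed=0)
    nets.classifier.lin.W.data = np.array([[50.0, -50.0], [-50.0, 50.0]])
    nets.classifier.lin.b.data[:] = 0.0
    z = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert float(classifier_loss(nets, z, ["a", "b"]).data) < 1e-8


def test_classifier_hand_arithmetic():
    nets = build_networks(3, 3, latent_dim=3, hidden=(4,), disc_hidden=(4,),
                          classes=["a", "b", "c"], seed=0)
    nets.classifier.lin.W.data = np.eye(3)
    nets.classifier.lin.b.data[:] = 0.0
    z = np.array([[1.0, 0.0, 0.0], [0.0, 2.0, 0.0], [0.0, 0.0, 3.0]])
    logits = z  # W = I
    logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
    expected = -np.mean([logp[0, 0], logp[1, 1], logp[2, 2]])
    got = float(classifier_loss(nets, z, ["a", "b", "c"]).data)
    assert got == pytest.approx(expected)


def test_classifier_unseen_label_errors():
    nets = build_networks(3, 3, latent_dim=2, hidden=(4,), disc_hidden=(4,),
                          classes=["a"], seed=0)
    with pytest.raises(ValueError, match="vocabulary"):
        classifier_loss(nets, np.zeros((1, 2)), ["zzz"])


# ------------------------------------------------------------------------ MMD
def test_mmd_identical_sets_zero(rng):
    x = rng.normal(size=(8, 3))
    assert float(mmd_loss(x, x.copy()).data) == 0.0


def test_mmd_separation_property(rng):
    base = rng.normal(size=(20, 2))
    interleaved = rng.normal(size=(20, 2))
    far = rng.normal(size=(20, 2)) + 10.0
    assert float(mmd_loss(base, far).data) > float(mmd_loss(base, interleaved).data)


def test_mmd_oracle_double_sum(rng):
    x, y = rng.normal(size=(5, 2)), rng.normal(size=(5, 2))
    bw = 1.3
    got = float(mmd_loss(x, y, bandwidths=(bw,)).data)

    def k(a, b):
        return np.exp(-np.sum((a - b) ** 2) / (2 * bw * bw))

    n = m = 5
    sxx = sum(k(x[i], x[j]) for i in range(n) for j in range(n) if i != j) / (n * (n - 1))
    syy = sum(k(y[i], y[j]) for i in range(m) for j in range(m) if i != j) / (m * (m - 1))
    sxy = sum(k(x[i], y[j]) for i in range(n) for j in range(m)) / (n * m)
    assert got == pytest.approx(max(0.0, sxx + syy - 2 * sxy))


def test_mmd_too_few_points_errors(rng):
    with pytest.raises(ValueError, match="at least 2"):
        mmd_loss(rng.normal(size=(1, 2)), rng.normal(size=(5, 2)))


# --------------------------------------------------------------------- anchor
def test_anchor_identical_latents_zero(rng):
    nets = _NetsStub()
    x = Tensor(rng.normal(size=(4, 3)))
    assert float(anchor_loss(nets, x, x).data) == 0.0


def test_anchor_single_pair_value():
    nets = _NetsStub()
    # mean squared distance per dim: ((1)^2+(2)^2)/2 = 2.5
    x = Tensor([[1.0, 2.0]])
    y = Tensor([[0.0, 0.0]])
    assert float(anchor_loss(nets, x, y).data) == pytest.approx(2.5)


def test_anchor_oracle_loop(rng):
    nets = build_networks(3, 4, latent_dim=2, hidden=(4,), disc_hidden=(4,), seed=2)
    xr, xa = rng.normal(size=(6, 3)), rng.normal(size=(6, 4))
    got = float(anchor_loss(nets, Tensor(xr), Tensor(xa)).data)
    zr = nets.encode(xr, "rna").coords
    za = nets.encode(xa, "atac").coords
    expected = np.mean([np.mean((zr[i] - za[i]) ** 2) for i in range(6)])
    assert got == pytest.approx(expected)


def test_anchor_unpaired_errors(rng):
    nets = _NetsStub()
    with pytest.raises(ValueError, match="paired"):
        anchor_loss(nets, Tensor(rng.normal(size=(3, 2))), Tensor(rng.normal(size=(4, 2))))


# ------------------------------------------------------------------ invariants
def test_losses_nonnegative_on_random_nets(rng):
    nets = build_networks(4, 5, latent_dim=3, hidden=(6,), disc_hidden=(4,),
                          classes=["a", "b"], seed=7)
    xr, xa = rng.normal(size=(6, 4)), rng.normal(size=(6, 5))
    labels = ["a", "b", "a", "b", "a", "b"]
    zr = nets.encode_t(Tensor(xr), "rna")
    za = nets.encode_t(Tensor(xa), "atac")
    disc, gen = adversarial_losses(nets, zr, za)
    values = [
        float(reconstruction_loss(nets, Tensor(xr), Tensor(xa)).data),
        float(cycle_consistency_loss(nets, Tensor(xr), Tensor(xa)).data),
        float(contrastive_loss(zr, labels, 1.0).data),
        float(classifier_loss(nets, zr, labels).data),
        float(mmd_loss(zr.data, za.data).data),
        float(anchor_loss(nets, Tensor(xr), Tensor(xa)).data),
        float(disc.data),
        float(gen.data),
    ]
    assert all(np.isfinite(v) and v >= 0.0 for v in values)


def test_distance_conventions(rng):
    a, b = Tensor(rng.normal(size=(3, 4))), Tensor(rng.normal(size=(3, 4)))
    diff = a.data - b.data
    np.testing.assert_allclose(
        rowwise_distance(a, b, "squared_l2").data, np.mean(diff**2, axis=1)
    )
    np.testing.assert_allclose(
        rowwise_distance(a, b, "l1").data, np.mean(np.abs(diff), axis=1)
    )
    np.testing.assert_allclose(
        rowwise_distance(a, b, "l2").data,
        np.sqrt(np.sum(diff**2, axis=1)) / 4.0,
        rtol=1e-6,
    )
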