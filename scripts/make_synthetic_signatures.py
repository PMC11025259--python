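"""Build the bundled synthetic 30-signature reference matrix.

The file ``src/wexscape/data/signatures_v2like_synthetic.tsv`` is a
synthetic stand-in for a 30-signature SBS96 reference catalog.  A handful
of signatures are constructed to mimic the qualitative structure of
well-known mutational processes (an age-related CpG C>T signature, two
APOBEC-like TpC signatures, a flat HR-deficiency-like signature, a
POLE-like T[C>A]T signature, an MMR-like C>T signature); the remainder
are sparse random simplex draws at a fixed seed.  Profiles are distinct
enough for refitting and matching to be well-posed.

Run from the repository root:  python scripts/make_synthetic_signatures.py
"""

import numpy as np
import pandas as pd

from wexscape.spectra import SBS96_LABELS

SEED = 20240601
N_SIG = 30
OUT = "src/wexscape/data/signatures_v2like_synthetic.tsv"


def channel_mask(sub=None, five=None, three=None):
    mask = np.zeros(96, dtype=bool)
    for i, lab in enumerate(SBS96_LABELS):
        f, rest = lab[0], lab[2:]
        s, t = rest[:3], rest[-1]
        if sub is not None and s != sub:
            continue
        if five is not None and f not in five:
            continue
        if three is not None and t not in three:
            continue
        mask[i] = True
    return mask


def normalize(v):
    v = np.clip(v, 0, None)
    return v / v.sum()


def main():
    rng = np.random.default_rng(SEED)
    profiles = {}

    # Age-related: C>T at NpCpG, with a modest C>T background.
    v = np.full(96, 0.05 / 96)
    v[channel_mask(sub="C>T", three="G")] += 0.85 / 16
    v[channel_mask(sub="C>T")] += 0.10 / 16
    profiles["Signature_1"] = normalize(v)

    # APOBEC-like C>T at TpCpW.
    v = np.full(96, 0.06 / 96)
    v[channel_mask(sub="C>T", five="T", three="AT")] += 0.94 / 2
    profiles["Signature_2"] = normalize(v)

    # HR-deficiency-like: near-flat with mild jitter.
    v = 1.0 + 0.2 * rng.random(96)
    profiles["Signature_3"] = normalize(v)

    # MMR-like: broad C>T plus T>C component.
    v = np.full(96, 0.08 / 96)
    v[channel_mask(sub="C>T")] += 0.60 / 16
    v[channel_mask(sub="T>C")] += 0.32 / 16
    profiles["Signature_6"] = normalize(v)

    # POLE-like: dominant T[C>A]T.
    v = np.full(96, 0.15 / 96)
    v[channel_mask(sub="C>A", five="T", three="T")] += 0.70
    v[channel_mask(sub="T>G", five="T", three="T")] += 0.15
    profiles["Signature_10"] = normalize(v)

    # APOBEC-like C>G at TpCpW.
    v = np.full(96, 0.06 / 96)
    v[channel_mask(sub="C>G", five="T", three="AT")] += 0.94 / 2
    profiles["Signature_13"] = normalize(v)

    # Remaining signatures: sparse random simplex draws.
    for k in range(1, N_SIG + 1):
        name = f"Signature_{k}"
        if name in profiles:
            continue
        v = rng.dirichlet(np.full(96, 0.08))
        profiles[name] = normalize(v + 1e-5)

    names = [f"Signature_{k}" for k in range(1, N_SIG + 1)]
    df = pd.DataFrame({n: profiles[n] for n in names}, index=list(SBS96_LABELS))
    df.index.name = "context"
    with open(OUT, "w") as fh:
        fh.write(
            "# SYNTHETIC stand-in reference signature matrix (30 x 96).\n"
            "# Constructed by scripts/make_synthetic_signatures.py at a fixed\n"
            "# seed; NOT the real COSMIC catalog.  Rows follow the canonical\n"
            "# SBS96 channel order; each column sums to 1.\n"
        )
        df.round(8).to_csv(fh, sep="\t")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
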