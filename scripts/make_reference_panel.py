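"""One-off: generate the bundled reference panel (receptor family + decoys)
and freeze it as plain FASTA package data. Receptors must show exactly 7
predicted TM helices; decoys are an unrelated 7TM-like family."""

import numpy as np
from tm7pop.mining.tm import predict_tm_helices

rng = np.random.default_rng(20190830)

HYDRO = list("ILVFMA")
POLAR = list("STNQEDKRGPHY")
CHARGED = list("EDKR")


def make_ancestor(rng, n_term=22, loop_lens=(14, 16, 15, 17, 14, 16), c_term=28, helix=23):
    parts = []
    parts.append("M" + "".join(rng.choice(POLAR, n_term - 1)))
    for k in range(7):
        parts.append("".join(rng.choice(HYDRO, helix)))
        if k < 6:
            loop = list(rng.choice(POLAR, loop_lens[k]))
            # guarantee charged flanks so windows die quickly outside helices
            loop[0], loop[-1] = rng.choice(CHARGED), rng.choice(CHARGED)
            parts.append("".join(loop))
    parts.append("".join(rng.choice(POLAR, c_term)))
    return "".join(parts)


def mutate(seq, rng, rate):
    out = list(seq)
    for i in range(1, len(out)):  # keep initial M
        if rng.random() < rate:
            pool = HYDRO if out[i] in HYDRO else POLAR
            out[i] = rng.choice(pool)
    return "".join(out)


v1r_anc = make_ancestor(rng)
decoy_anc = make_ancestor(rng, n_term=30, loop_lens=(15, 14, 17, 16, 15, 14), c_term=35, helix=22)

records = []
for i in range(8):
    p = mutate(v1r_anc, rng, 0.10)
    count, spans = predict_tm_helices(p)
    assert count == 7, (i, count, spans)
    records.append((f"v1r{i+1}|v1r", p))
for i in range(5):
    p = mutate(decoy_anc, rng, 0.10)
    count, spans = predict_tm_helices(p)
    assert count == 7, ("decoy", i, count)
    records.append((f"gpcrdecoy{i+1}|decoy", p))

# check cross-family dissimilarity at the aa level (rough: identity of aligned positions)
from tm7pop.mining.search import make_aligner
al = make_aligner()
within = al.score(records[0][1], records[1][1])
cross = al.score(records[0][1], records[8][1])
print("len", len(v1r_anc), "within-family score", within, "cross-family score", cross)
assert within > 2 * cross, (within, cross)

with open("src/tm7pop/data/reference_panel.fa", "w") as fh:
    for rid, seq in records:
        fh.write(f">{rid}\n{seq}\n")
print("wrote", len(records), "proteins")
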