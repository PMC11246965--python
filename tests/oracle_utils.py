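"""Independent brute-force restatement of the species-change rules.

Shared by the unit and acceptance suites as the oracle the scenario
engine is compared against; deliberately written without reusing any
engine code (hardcoded trait sets, explicit enumeration).
"""

import numpy as np

from forest_adapt.registry import load_registry

REG = load_registry()

def oracle_apply(shares, volume, suit, label):
    """Brute-force restatement of the replacement rules.

    ``suit`` maps species -> relative suitability (>= 1 means suitable)
    for every species with a record.  Enumerates every failing species
    and candidate receiver explicitly; kept free of the engine's code.
    """
    native = {"aal", "fsy", "lde", "pab", "psy", "que"}
    conifer = {"aal", "lde", "pab", "psy", "agr", "pco", "pra", "pme", "tpl"}
    inc = {p.code: p.increment_std for p in REG}

    occurring = [s for s, v in shares.items() if v > 0]
    failing = [s for s in occurring if suit[s] < 1.0]
    survivors = {s: shares[s] for s in occurring if suit[s] >= 1.0}
    new = dict(survivors)
    lost = 0.0
    total = sum(shares[s] for s in occurring)

    if label == "no_adaptation":
        surv_total = sum(survivors.values())
        for f in failing:
            if surv_total > 0:
                for s in survivors:
                    new[s] += shares[f] * survivors[s] / surv_total
            # the failing stock is lost either way
        out_volume = volume * (surv_total / total) if total else 0.0
    else:
        pool = native if label.startswith("native") else set(REG.codes)
        form_first = label.endswith("ccbb")
        for f in failing:
            candidates = [c for c in pool if c in suit and suit[c] >= 1.0 and c != f]
            chosen = None
            if form_first:
                same = [c for c in candidates if (c in conifer) == (f in conifer)]
                if same:
                    candidates = same
            best = None
            for c in candidates:
                key = (suit[c], inc[c], [-ord(ch) for ch in c])
                if best is None or key > best:
                    best, chosen = key, c
            if chosen is None:
                lost += shares[f]
            else:
                new[chosen] = new.get(chosen, 0.0) + shares[f]
        out_volume = volume * ((total - lost) / total) if total else 0.0

    new = {s: v for s, v in new.items() if v > 0}
    unstocked = sum(new.values()) == 0
    if unstocked:
        out_volume = 0.0
    return new, out_volume, unstocked


def _random_case(rng):
    codes = list(REG.codes)
    occurring = rng.choice(codes, size=rng.integers(1, 4), replace=False).tolist()
    raw = rng.dirichlet(np.ones(len(occurring)))
    shares = {s: float(v) for s, v in zip(occurring, raw)}
    extra = [c for c in codes if c not in occurring]
    candidates = rng.choice(extra, size=rng.integers(0, 6), replace=False).tolist()
    # coarse probabilities force frequent ties to exercise tie-breaking
    suit = {
        s: float(rng.choice([0.0, 20.0, 40.0, 60.0, 60.0, 80.0, 100.0])) / REG.cutoff(s)
        for s in occurring + candidates
    }
    volume = float(rng.uniform(0.0, 800.0))
    return shares, volume, suit


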