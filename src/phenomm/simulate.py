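"""Seedable generator of multi-batch mouse phenotyping studies.

The generator draws data with exactly the structure the mixed model assumes:
iid Gaussian batch intercepts, iid Gaussian residuals, and a trait that is a
linear function of genotype, sex and body weight,

    weight_i = weight_mean(sex) + gamma_weight * knockout_i + N(0, weight_sd^2)
    trait_i  = beta0 + beta1_direct * knockout_i + beta2 * male_i
               + beta3 * weight_i + beta4 * knockout_i * male_i
               + u_batch(i) + N(0, sigma_e^2(genotype))

Mutants occupy a small number of batches of their own by default
(asynchronous controls — in a high-throughput pipeline mutants and controls
are typically not assayed on the same day), which is precisely the layout
under which pooled two-group tests break down.

Named scenarios package the parameter settings used throughout the test
suite: a batch-confounded null, a direct genotype effect, a weight-mediated
effect, a weight-reversed effect, and a no-batch-variation control.  Default
magnitudes are on a DEXA fat-mass-like scale (trait in grams, body weight
~22–28 g) and are sized so that batch explains roughly a quarter of control
trait variance, echoing what large control archives show.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .data import FEMALE, KNOCKOUT, MALE, PhenotypeRecord, WILDTYPE
from .errors import ValidationError


@dataclass
class SimConfig:
    """Generating parameters for one simulated study.

    Counts mirror a high-throughput pipeline: a weekly control cohort and a
    small mutant cohort spread over a few assay days (7 animals per sex,
    entering the pipeline in batches as breeding allows).  ``sigma_e`` may be
    a single residual SD or a ``(wildtype, knockout)`` pair.
    """

    seed: int = 0
    # layout
    n_batches_control: int = 20
    batch_size_control: int = 5
    n_mutants_per_sex: int = 7
    n_mutant_batches: int = 4
    mutant_batches_shared_with_controls: bool = False
    # variance components (trait units)
    sigma_u: float = 0.7
    sigma_e: float | tuple[float, float] = 1.0
    # generating fixed effects (trait units; beta3 in units per gram)
    beta0: float = 8.0
    beta1_direct: float = 0.0
    beta2: float = 1.0
    beta3: float = 0.25
    beta4: float = 0.0
    # body weight model (grams)
    gamma_weight: float = 0.0
    weight_mean_by_sex: tuple[float, float] = (22.0, 28.0)  # (female, male)
    weight_sd: float = 2.5
    trait_name: str = "fat_mass"

    def __post_init__(self):
        sde = self.sigma_e if isinstance(self.sigma_e, tuple) else (self.sigma_e,)
        if self.sigma_u < 0 or any(s < 0 for s in sde) or self.weight_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        for name in ("n_batches_control", "batch_size_control",
                     "n_mutants_per_sex", "n_mutant_batches"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")

    def sigma_e_for(self, knockout: bool) -> float:
        if isinstance(self.sigma_e, tuple):
            return self.sigma_e[1 if knockout else 0]
        return self.sigma_e


def _batch_label(index: int) -> str:
    # ISO-date labels one week apart so diagnostics can order batches in time
    base = np.datetime64("2010-01-04")
    return str(base + np.timedelta64(7 * index, "D"))


def generate_dataset(config: SimConfig) -> list[PhenotypeRecord]:
    """Generate one study: control cohorts plus a mutant cohort.

    Identical configs produce identical tables.  The seed is split into
    independent child streams (batch effects, weights, trait noise) so that
    changing the number of animals perturbs only the affected stream.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_batch, rng_weight, rng_noise = (
        np.random.default_rng(c) for c in ss.spawn(3)
    )

    n_cb = config.n_batches_control
    if config.mutant_batches_shared_with_controls:
        if config.n_mutant_batches > n_cb:
            raise ValidationError("cannot share more mutant batches than exist")
        n_total_batches = n_cb
        mutant_batch_ids = list(range(n_cb - config.n_mutant_batches, n_cb))
    else:
        n_total_batches = n_cb + config.n_mutant_batches
        mutant_batch_ids = list(range(n_cb, n_total_batches))

    u = rng_batch.normal(0.0, config.sigma_u, n_total_batches)

    def make_animal(idx: int, knockout: bool, sex: str, batch_id: int):
        wmean = config.weight_mean_by_sex[0 if sex == FEMALE else 1]
        w = wmean + (config.gamma_weight if knockout else 0.0) \
            + rng_weight.normal(0.0, config.weight_sd)
        w = max(w, 1.0)  # body weight is physically positive
        y = (config.beta0
             + config.beta1_direct * knockout
             + config.beta2 * (sex == MALE)
             + config.beta3 * w
             + config.beta4 * knockout * (sex == MALE)
             + u[batch_id]
             + rng_noise.normal(0.0, config.sigma_e_for(knockout)))
        return PhenotypeRecord(
            animal_id=f"{'ko' if knockout else 'wt'}{idx:04d}",
            genotype=KNOCKOUT if knockout else WILDTYPE,
            sex=sex, batch=_batch_label(batch_id), weight=w,
            traits={config.trait_name: float(y)},
        )

    records = []
    idx = 0
    for b in range(n_cb):
        for k in range(config.batch_size_control):
            sex = FEMALE if k % 2 == 0 else MALE
            records.append(make_animal(idx, False, sex, b))
            idx += 1
    # mutants round-robin over their batches, both sexes present in each
    mutants = [(FEMALE, i) for i in range(config.n_mutants_per_sex)] + \
              [(MALE, i) for i in range(config.n_mutants_per_sex)]
    for k, (sex, _) in enumerate(mutants):
        records.append(make_animal(idx, True, sex,
                                   mutant_batch_ids[k % len(mutant_batch_ids)]))
        idx += 1
    return records


SCENARIOS = ("null_confounded", "direct_effect", "weight_mediated",
             "reversed_after_weight", "no_batch")


def scenario(name: str, seed: int = 0) -> SimConfig:
    """Named study configurations demonstrating the pipeline's behaviour.

    null_confounded
        No genotype effect anywhere, batch SD equal to residual SD, mutants
        in their own batches — the layout in which a pooled t-test produces
        spurious genotype calls while the mixed model stays calibrated.
    direct_effect
        A genuine genotype effect on the trait (beta1_direct = 1.5, batch
        and residual SD 1.0) with no body-weight involvement.
    weight_mediated
        The knockout shifts body weight (-4 g) and the trait tracks weight
        (0.4 trait units per gram); no direct genotype effect, so the eq1
        call should vanish once weight enters the model.
    reversed_after_weight
        A dwarf-like weight loss (-9 g) whose mediated trait decrease
        (0.5 x -9 = -4.5) is partially offset by a direct increase (+2.4):
        the trait drops overall but is higher than its weight predicts, so
        eq1 calls a decrease and eq2 an increase.  Magnitudes are sized for
        ~90% power of each component call at the cohort sizes above, so the
        joint pattern appears in a clear majority of replicates.
    no_batch
        sigma_u = 0; step 1 should drop the random intercept.
    """
    base = dict(seed=seed)
    table = {
        "null_confounded": dict(sigma_u=1.0, sigma_e=1.0, beta3=0.0),
        "direct_effect": dict(sigma_u=1.0, sigma_e=1.0, beta3=0.0,
                              beta1_direct=1.5),
        "weight_mediated": dict(gamma_weight=-4.0, beta3=0.4),
        "reversed_after_weight": dict(gamma_weight=-9.0, beta3=0.5,
                                      beta1_direct=2.4),
        "no_batch": dict(sigma_u=0.0),
    }
    if name not in table:
        raise ValidationError(
            f"unknown scenario {name!r}; choose from {SCENARIOS}"
        )
    return SimConfig(**base, **table[name])


def config_to_dict(config: SimConfig) -> dict:
    """JSON-serialisable view of a config, for provenance files."""
    d = dataclasses.asdict(config)
    if isinstance(d["sigma_e"], tuple):
        d["sigma_e"] = list(d["sigma_e"])
    d["weight_mean_by_sex"] = list(d["weight_mean_by_sex"])
    return d
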