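# Methods

## Scope and intent

`cannrisk` implements a *first-tier* (screening-level) toxicological risk
assessment for ingredients intentionally added to THC-containing cannabis
concentrates that are vaporized. It is deliberately conservative and
deliberately simple: its job is triage — accept, eliminate, or escalate to
an expert — not to produce refined risk estimates. Cannabinoids themselves,
contaminants (solvents, pesticides, metals), aerosol degradation chemistry,
mixture interactions, read-across, benchmark-dose modelling and PBK
modelling are out of scope; several of those are exactly what the "escalate"
outcome is for.

## The dossier as the unit of input

All chemistry-dependent judgments (respiratory-sensitizer status, genotoxicity
alerts, Cramer class, OASIS mode of action, TTC exclusion categories) are
*asserted inputs*, typically transcribed from Safety Data Sheets, regulatory
classifications, or the free classification tools (ToxTree, OECD QSAR
Toolbox). The package validates and routes; it never infers hazard from
structure. Hazard booleans absent from an input file default to `false` but
are logged as "not asserted" so the audit trail distinguishes an affirmative
claim from silence. Exculpatory flags (`gras_or_food_use`,
`developmental_data_available`) also default to `false`, so conservatism is
the default posture.

Two tri-state/optional fields matter for limit derivation:

* `developmental_structural_alert` — `None` (not assessed) is treated like
  `True`: the database uncertainty factor stays at 10 for non-age-gated
  products. Only an explicit `False` (structure not suggestive of
  developmental toxicity) relaxes it to 3.
* `PodRecord.oral_to_inhalation_absorption_ratio` — when a measured
  absorption ratio is supplied it replaces the default toxicokinetic
  component (factor 2) of the route-extrapolation factor, which drops from
  6 to 3, and the adjusted POD is scaled by the ratio.

## Screening rules

Exclusions (any one suffices; all triggered rules are reported, no
short-circuit): non-native respiratory sensitizers; Big-8 allergen sources;
phenolic acetates; supplements/vitamins/HPHCs. Cannabis-native sensitizers
get a concentration cap of `plant_ratio_to_thc × product THC (mg/g)`; if the
dossier asserts a native sensitizer without a plant ratio, screening raises
an error demanding the datum rather than inventing a cap — this is the one
place screening is not total, because a cap verdict without a cap value
would be meaningless. Formulating exactly at the cap is allowed with a
boundary warning in the audit log; above it, the verdict is an exceedance
regardless of the toxicological limit. Genotoxicity or a carcinogen listing
attaches a route-to-genotoxic-TTC reason; with `strict_genotoxicity=True`
it excludes instead.

## Limit derivation choices

* **Schedule adjustment.** Oral PODs are multiplied by `days/7` only —
  hours per day are irrelevant to a daily oral dose. Inhalation PODs are
  additionally multiplied by `hours/24`, making them continuous-equivalent
  concentrations; they are therefore normalized to mg/day with the 20 m³
  24-h inhalation volume. Regulatory limits are *not* schedule-adjusted:
  they are converted with the inhalation volume of their stated averaging
  window (0.3 m³ / 15 min, 6.7 m³ / 8-h workday, 20 m³ / 24 h), and any UF
  categories the issuing body already addressed are forced to 1 with
  provenance "addressed by source limit".
* **Dermal PODs are rejected** with an error: no defensible extrapolation
  factors exist at this tier, and refusing is safer than inventing them.
* **LD50/LC50 are unrepresentable** — the POD-type enumeration simply has
  no lethality members, making the misuse inexpressible.
* **Intraspecies relief (UF2 = 3 or 1) is never automatic**; it requires an
  explicit `tested_sensitive_subpopulation` assertion on the POD.
* **UF cap.** A total UF above 10,000 raises `InsufficientDataError`. In the
  orchestrated pipeline such a POD is discarded (with an audit entry) and
  the assessment falls back to TTC; if TTC is also unavailable the verdict
  is `insufficient_data` — never a silent pass.
* **Governing.** Systemic and local-respiratory candidates are ranked
  separately; within a track a NOAEL/NOAEC candidate is discarded when its
  adjusted, mg/day-normalized POD exceeds some LOAEL's — the comparison is
  done on normalized PODs because candidates may carry different native
  units. The minimum normalized limit across surviving candidates governs.
* **Units.** TTC limits (µg/day) cross into mg/day through a single
  conversion choke point (`cannrisk.units`); nothing else in the codebase
  multiplies or divides by 1000 for this purpose. Limits keep full floating
  precision internally; reports display 3 significant figures.

## TTC routing

The five questions are evaluated strictly in printed order and the first
match answers: an organophosphate that is also GRAS keeps 18 µg/day, and an
unknown Cramer class behind an earlier match is harmless. Reaching Q4 with
an unknown Cramer class (or Q5 with an unknown OASIS MOA) is an error
naming the classification tools, not a guess. A `conservative=True` mode
collects every matching branch and returns the minimum, reflecting the
advice to run multiple models and keep the lower value; it is off by
default to match the printed tree. The µg/day values live in a versioned
JSON data file (`cannrisk/data/ttc_limits.json`) so regulators can audit or
override them; routing verifies nothing about the numbers beyond positivity.
A carcinogen listing *without* a genotoxicity alert does not trigger the
genotoxic tier — it logs a warning recommending expert review and proceeds,
since the tier is defined by genotoxic potential.

## Exposure assessment

Defaults: 100 mg concentrate/day, 100% bioavailability (bioavailability is
configurable but enters only the THC cross-check utility, never the additive
exposure), 60 kg body weight, 20 / 6.7 / 0.3 m³ inhalation volumes, 30.5
days/month. The 100 mg/day constant is derived, not asserted:
`recommended_daily_consumption` averages the 95th-percentile weekly and
monthly daily averages (140 and 57 mg/day → 98.5) and rounds to one
significant figure for the headline.

Usage-log summaries: daily statistics pool use days only (consumed > 0);
weekly and monthly statistics pool calendar-window totals (ISO weeks;
calendar months) across devices, zero-filling windows without records
inside each device's first-to-last observation span, so non-use days count.
Devices are treated as users. Percentiles are empirical quantiles with
linear interpolation between order statistics — the most widely reproduced
convention. Partial windows at the span edges are included as-is.

## The telemetry simulator

The simulator emulates the two features of real smart-vaporizer telemetry
that drive exposure: intermittency and heavy-tailed consumption.

* Monthly use-day counts are geometric (negative binomial, shape 1) with
  mean 7.8. This single-parameter choice is not arbitrary: with mean 7.8 a
  geometric distribution has median 5 and 95th percentile 24, matching all
  three published frequency statistics at once. The first month is
  zero-truncated so every device appears in the log; later months may be
  silent. Counts are capped at the days available in the month window.
* Use days are placed uniformly at random within each month; per-use-day
  consumption is i.i.d. log-normal with location `ln(median)` and scale
  `sqrt(2·ln(mean/median))` — the closed-form inversion giving exactly the
  requested median (44 mg) and mean (151 mg). σ ≈ 1.571 at the defaults.
* Identical parameters and seed give byte-identical logs
  (`numpy.random.default_rng`).

What it does **not** emulate: within-device autocorrelation (no published
dependence structure), device sharing, seasonal trends, or the ~20%
estimation error of the underlying puff-mass model. Consequently the
simulator's weekly/monthly *percentile* statistics land near but not on the
published table (the daily-row calibration and the frequency process are
honored; the weekly/monthly tails emerge from the independence assumptions),
and tests treat only the calibrated daily statistics and use-day frequency
as recovery targets (within 10% at 10,000 devices). Passing tests show the
pipeline arithmetic is right under realistic structure — not that the
synthetic population reproduces any real user base.

Default horizon: 3 calendar months (90 days from 2021-01-01), long enough
for weekly and monthly summaries in one run.

## Numerical conventions and degenerate inputs

* Exposure equal to the limit is low risk (≤ convention) with a boundary
  warning logged; the comparison is measure-zero and the warning keeps the
  conservatism visible.
* `max_allowable_concentration` caps at 100% w/w with a warning when the
  back-calculation exceeds it; zero consumption is an error.
* An all-zero usage log (no use days) and an empty log are errors, not
  empty summaries.
* Zero simulated devices yields an empty log, not an error.
* One-significant-figure headline rounding uses `round(x/10^⌊log10 x⌋)`;
  98.5 → 100, 60 → 60.

## Known limitations

Beyond the out-of-scope list above: the 60 kg body weight is the only
supported weight (age-gated products make child scenarios out of scope);
whether a human clinical study counts as "chronic" is the dossier author's
call; plant-relative sensitizer caps take the inflorescence ratio as given
without specifying a dry-weight basis; and the framework inherits the
conservatism of every default it stacks, which is intentional for tier one
but means an `exceeds_limit` verdict is a prompt for refinement, not a
finding of harm.
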