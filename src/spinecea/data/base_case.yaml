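# Base-case configuration: published estimates for privately insured,
# working-age patients (2009 USD). Every entry equals the package default;
# copy this file and override selectively via `spinecea run --params FILE`.

clinical:
  p_satisfactory_surgical: 0.753        # satisfied after primary surgery
  p_satisfactory_nonsurgical: 0.485     # satisfied after nonsurgical care
  p_satisfactory_after_revision: 0.753  # same success as primary surgery
  revision_rate_year1: 0.06             # first year after surgery
  revision_rate_subsequent: 0.03        # per year thereafter
  surgical_mortality: 0.0013            # per operation
  max_revisions: 2

utilities:
  satisfactory: 0.89
  unsatisfactory: 0.56
  revision: 0.69                        # temporary revision-year state
  dead: 0.0

costs:
  surgery_cost_blended: 16423.0         # inpatient/outpatient mix
  surgery_cost_inpatient: 20585.0
  surgery_cost_outpatient: 11616.0
  annual_medical_cost_surgical: 3208.0  # excluding the surgery itself
  annual_medical_cost_nonsurgical: 3794.0

timing:
  discount_rate: 0.03
  utilities: cycle_start
  annual_costs: cycle_start
  offsets: cycle_start
  offsets_survival_weighted: true
  recovery_timing: cycle_0

# life_table: path/to/age_qx.csv       # columns age,qx; packaged synthetic
#                                      # US-magnitude table used when omitted
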