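# Exposure-response curve registry: percent of the population highly annoyed
# (%HA, versus Ldn) or highly sleep disturbed (%HSD, versus Lnight).
#
# Families:
#   logistic            -> 100 / (1 + exp(a - b*L)),        coefficients [a, b]
#   polynomial          -> c0 + c1*L + c2*L^2 + ...,        coefficients [c0, c1, ...]
#   polynomial_shifted  -> sum_i c_i*(L - s)^i  (i >= 1),   coefficients [s, c1, c2, ...]
#
# Outside [domain_lo, domain_hi] the response is zero below and capped at the
# domain-top value above.  Curves marked native_metric: Lden are evaluated on
# Ldn by the pipeline (the standard US practice when no evening penalty is
# modelled), which slightly understates the response; consumers are warned.
#
# Provenance: FICON, ISO and the two WHO curves are transcribed verbatim from
# their published coefficient sets.  The NES, Yokoshima and Smith entries are
# monotone fits through widely quoted summary points of the published curves
# (the primary coefficient tables were not redistributable); treat them as
# faithful approximations, not verbatim transcriptions.
version: 1
transcribed: 2026-09-22
curves:
  - name: FICON
    outcome: annoyance
    metric: Ldn
    native_metric: Ldn
    family: logistic
    coefficients: [11.13, 0.141]
    domain: [45.0, 90.0]
    source: >
      Federal Interagency Committee on Noise (1992) dose-response curve for
      community annoyance; %HA = 100/(1+exp(11.13-0.141*Ldn)).
  - name: ISO
    outcome: annoyance
    metric: Ldn
    native_metric: Lden
    family: polynomial_shifted
    coefficients: [42.0, 0.2939, 0.03932, -0.00009199]
    domain: [45.0, 75.0]
    source: >
      ISO 1996-1:2016 Annex F aircraft curve (Miedema & Oudshoorn 2001):
      %HA = -9.199e-5*(Lden-42)^3 + 3.932e-2*(Lden-42)^2 + 0.2939*(Lden-42).
  - name: WHO
    outcome: annoyance
    metric: Ldn
    native_metric: Lden
    family: polynomial
    coefficients: [-50.9693, 1.0168, 0.0072]
    domain: [45.0, 75.0]
    source: >
      WHO Environmental Noise Guidelines for the European Region (2018),
      aircraft %HA full-dataset quadratic (Guski et al. 2017).
  - name: NES
    outcome: annoyance
    metric: Ldn
    native_metric: Ldn
    family: logistic
    coefficients: [5.92, 0.0953]
    domain: [45.0, 75.0]
    source: >
      FAA Neighborhood Environmental Survey national annoyance curve (2021);
      logistic fit through published summary points (approximate transcription).
  - name: Yokoshima
    outcome: annoyance
    metric: Ldn
    native_metric: Lden
    family: logistic
    coefficients: [8.86, 0.1523]
    domain: [45.0, 75.0]
    source: >
      Yokoshima et al. synthesis of military aircraft noise annoyance surveys
      (US forces / Japan Self-Defense Forces airfields); logistic fit through
      published summary points (approximate transcription).
  - name: WHO_sleep
    outcome: sleep_disturbance
    metric: Lnight
    native_metric: Lnight
    family: polynomial
    coefficients: [16.7885, -0.9293, 0.0198]
    domain: [40.0, 65.0]
    source: >
      WHO Environmental Noise Guidelines (2018), aircraft %HSD quadratic
      (Basner & McGuire 2018).
  - name: Smith_sleep
    outcome: sleep_disturbance
    metric: Lnight
    native_metric: Lnight
    family: polynomial
    coefficients: [19.4, -1.05, 0.022]
    domain: [40.0, 65.0]
    source: >
      Smith et al. updated aircraft %HSD curve including post-2018 survey
      data; quadratic fit through published summary points (approximate
      transcription).
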