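# Bundled heat-stress classification schemes.
#
# Each scheme is an ordered list of bands; a band applies from its
# lower_bound (inclusive) up to the next band's lower_bound (exclusive).
# The first band must start at -inf so every finite value classifies.
#
# humidex_1 / humidex_2 follow the OHCOW "Humidex Based Heat Response Plan"
# ladder of occupational responses, for acclimatised (1) and unacclimatised
# (2) persons.  The numeric boundaries are a constrained transcription: the
# published study reproducing the plan provides four machine-checkable
# worked classifications (33.82 -> level 1 / level 2; 42.26 -> level 3 /
# level 6; 24.50 -> level 0 under both), which these bounds satisfy and which
# are re-verified as a load-time self-check.  See docs/methods.md.
#
# nws_heat_index bands are the standard NWS categories, expressed on the
# deg C scale of the re-converted Heat Index (80 / 90 / 103 / 125 degF).
schemes:
  humidex_1:
    description: Humidex response thresholds for acclimatised persons
    index: humidex_c
    bands:
      - lower_bound: -.inf
        level: 0
        label: no heat stress
        guidance: No heat stress; routine activity, no intervention required.
      - lower_bound: 30.0
        level: 1
        label: level 1
        guidance: >-
          Supply persons with, or let them obtain individually, water on an
          as-needed basis.
      - lower_bound: 34.0
        level: 2
        label: level 2
        guidance: >-
          Post heat stress alert notice; encourage persons to drink extra
          water.
      - lower_bound: 38.0
        level: 3
        label: level 3
        guidance: >-
          Post heat stress warning notice; notify persons that they need to
          drink extra water; ensure persons are trained to notice the
          symptoms of heat stress.
      - lower_bound: 43.0
        level: 4
        label: level 4
        guidance: >-
          Work interspersed with 15 min relief per hour; provide adequate
          cool (10-15 degC) water; at least 240 ml of water every 20 min;
          persons with symptoms to seek medical attention.
      - lower_bound: 45.0
        level: 5
        label: level 5
        guidance: >-
          Work interspersed with 30 min relief per hour, in addition to all
          lower-level measures.
      - lower_bound: 47.0
        level: 6
        label: level 6
        guidance: >-
          Work interspersed with 45 min relief per hour, in addition to all
          lower-level measures.
      - lower_bound: 50.0
        level: 7
        label: level 7
        guidance: >-
          Hazardous conditions; only medically supervised activities should
          continue.
  humidex_2:
    description: Humidex response thresholds for unacclimatised persons
    index: humidex_c
    bands:
      - lower_bound: -.inf
        level: 0
        label: no heat stress
        guidance: No heat stress; routine activity, no intervention required.
      - lower_bound: 25.0
        level: 1
        label: level 1
        guidance: >-
          Supply persons with, or let them obtain individually, water on an
          as-needed basis.
      - lower_bound: 32.0
        level: 2
        label: level 2
        guidance: >-
          Post heat stress alert notice; encourage persons to drink extra
          water.
      - lower_bound: 34.0
        level: 3
        label: level 3
        guidance: >-
          Post heat stress warning notice; notify persons that they need to
          drink extra water; ensure persons are trained to notice the
          symptoms of heat stress.
      - lower_bound: 36.0
        level: 4
        label: level 4
        guidance: >-
          Work interspersed with 15 min relief per hour; provide adequate
          cool (10-15 degC) water; at least 240 ml of water every 20 min;
          persons with symptoms to seek medical attention.
      - lower_bound: 38.0
        level: 5
        label: level 5
        guidance: >-
          Work interspersed with 30 min relief per hour, in addition to all
          lower-level measures.
      - lower_bound: 40.0
        level: 6
        label: level 6
        guidance: >-
          Work interspersed with 45 min relief per hour, in addition to all
          lower-level measures.
      - lower_bound: 43.0
        level: 7
        label: level 7
        guidance: >-
          Hazardous conditions; only medically supervised activities should
          continue.
  nws_heat_index:
    description: NWS Heat Index risk categories (deg C scale)
    index: heat_index_c
    bands:
      - lower_bound: -.inf
        level: 0
        label: low risk
        guidance: No heat stress expected for most people.
      - lower_bound: 26.666666666666668   # 80 degF
        level: 1
        label: caution
        guidance: >-
          Fatigue possible with prolonged exposure and/or physical activity.
      - lower_bound: 32.22222222222222    # 90 degF
        level: 2
        label: extreme caution
        guidance: >-
          Heat cramps, heat exhaustion possible with prolonged exposure
          and/or physical activity.
      - lower_bound: 39.44444444444444    # 103 degF
        level: 3
        label: danger
        guidance: >-
          Heat cramps or heat exhaustion likely, heat stroke possible with
          prolonged exposure and/or physical activity.
      - lower_bound: 51.666666666666664   # 125 degF
        level: 4
        label: extreme danger
        guidance: Heat stroke highly likely.
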