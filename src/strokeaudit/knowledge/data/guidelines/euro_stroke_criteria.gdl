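-- guideline euro_stroke_criteria
guideline_id = <"euro_stroke_criteria">
description = <"Sampled compliance criteria from the European guidelines for ischaemic stroke management: MRI justification, thrombolysis indication, 72-hour temperature monitoring with a 37.5 C pyrexia alert, and oxygen administration below 95% saturation.">
definition = <
    gt0003 = <
        archetype_id = <"openEHR-EHR-EVALUATION.problem_diagnosis">
        path = <"/data[at0001]/items[at0002.1]">
        direction = <"input">
    >
    gt0004 = <
        archetype_id = <"openEHR-EHR-EVALUATION.problem_diagnosis">
        path = <"/data[at0001]/items[at0003]">
        direction = <"input">
    >
    gt0030 = <
        archetype_id = <"openEHR-EHR-OBSERVATION.exam">
        path = <"/data[at0001]/items[at0010]">
        direction = <"input">
    >
    gt0031 = <
        archetype_id = <"openEHR-EHR-INSTRUCTION.imaging">
        path = <"/activities[at0001]/description[openEHR-EHR-ITEM_TREE.imaging]/items[at0002]">
        direction = <"input">
    >
    gt0032 = <
        archetype_id = <"openEHR-EHR-OBSERVATION.indirect_oximetry">
        path = <"/data[at0001]/items[at0006]">
        direction = <"input">
    >
    gt0033 = <
        archetype_id = <"openEHR-EHR-OBSERVATION.body_temperature">
        path = <"/data[at0001]/items[at0004]">
        direction = <"input">
    >
    gt0034 = <
        archetype_id = <"openEHR-EHR-OBSERVATION.body_temperature">
        path = <"/data[at0001]/items[at0005]">
        direction = <"input">
    >
    gt0040 = <
        archetype_id = <"openEHR-EHR-EVALUATION.alert">
        path = <"/data[at0001]/items[at0002]">
        direction = <"output">
    >
    gt0041 = <
        archetype_id = <"openEHR-EHR-EVALUATION.alert">
        path = <"/data[at0001]/items[at0003]">
        direction = <"output">
    >
    gt0042 = <
        archetype_id = <"openEHR-EHR-EVALUATION.alert">
        path = <"/data[at0001]/items[at0004]">
        direction = <"output">
    >
    gt0043 = <
        archetype_id = <"openEHR-EHR-EVALUATION.alert">
        path = <"/data[at0001]/items[at0005]">
        direction = <"output">
    >
    gt0044 = <
        archetype_id = <"openEHR-EHR-EVALUATION.alert">
        path = <"/data[at0001]/items[at0006]">
        direction = <"output">
    >
    gt0045 = <
        archetype_id = <"openEHR-EHR-ACTION.procedure">
        path = <"/description[openEHR-EHR-ITEM_TREE.gas_administration]/items[at0001]">
        direction = <"output">
    >
    gt0046 = <
        archetype_id = <"openEHR-EHR-ACTION.procedure">
        path = <"/description[openEHR-EHR-ITEM_TREE.gas_administration]/items[at0002]">
        direction = <"output">
    >
>
rules = <
    mri_justified_set_false = <
        priority = <20>
        when = <"!($gt0030 is_a local::gt0130|posterior circulation variety or uncommon aetiology|)", "!($gt0031 is_a local::gt0131|stroke mimic suspected|)">
        then = <"$gt0040 = false">
    >
    mri_justified_set_true = <
        priority = <10>
        when = <"$gt0030 is_a local::gt0130|posterior circulation variety or uncommon aetiology| || $gt0031 is_a local::gt0131|stroke mimic suspected|">
        then = <"$gt0040 = true">
    >
    thrombolysis_indicated_set_false = <
        priority = <20>
        when = <"!($gt0030 is_a local::gt0132|acute ischaemic deficit| && $gt0003 is_a local::gt0102|stroke| && $gt0004 + PT4H30M >= currentDateTime)">
        then = <"$gt0041 = false">
    >
    thrombolysis_indicated_set_true = <
        priority = <10>
        when = <"$gt0030 is_a local::gt0132|acute ischaemic deficit|", "$gt0003 is_a local::gt0102|stroke|", "$gt0004 + PT4H30M >= currentDateTime">
        then = <"$gt0041 = true">
    >
    temperature_monitored_set_false = <
        priority = <20>
        when = <"$gt0003 is_a local::gt0102|stroke|", "!($gt0034 >= $gt0004 && $gt0034 <= $gt0004 + PT72H)">
        then = <"$gt0042 = false">
    >
    temperature_monitored_set_true = <
        priority = <10>
        when = <"$gt0003 is_a local::gt0102|stroke|", "$gt0034 >= $gt0004 && $gt0034 <= $gt0004 + PT72H">
        then = <"$gt0042 = true">
    >
    pyrexia_set_false = <
        priority = <20>
        when = <"$gt0003 is_a local::gt0102|stroke|", "$gt0034 >= $gt0004 && $gt0034 <= $gt0004 + PT72H", "$gt0033 <= 37.5">
        then = <"$gt0043 = false">
    >
    pyrexia_set_true = <
        priority = <10>
        when = <"$gt0003 is_a local::gt0102|stroke|", "$gt0034 >= $gt0004 && $gt0034 <= $gt0004 + PT72H", "$gt0033 > 37.5">
        then = <"$gt0043 = true">
    >
    oxygen_set_false = <
        priority = <20>
        when = <"$gt0032 >= 95">
        then = <"$gt0044 = false">
    >
    oxygen_set_true = <
        priority = <10>
        when = <"$gt0032 < 95">
        then = <"$gt0044 = true", "$gt0045 = SNOMED-CT::24099007|Oxygen gas|", "$gt0046 = local::at0006|Nasal canula|">
    >
>
term_groups = <
    gt0102 = <
        text = <"stroke">
        bindings = <
            ["SNOMED-CT"] = <"230690007">
            ICD10 = <"I64">
        >
    >
    gt0130 = <
        text = <"posterior circulation variety or uncommon aetiology">
        bindings = <
            ["SNOMED-CT"] = <"429993008">
        >
    >
    gt0131 = <
        text = <"stroke mimic suspected">
        bindings = <
            ["SNOMED-CT"] = <"373930000">
        >
    >
    gt0132 = <
        text = <"acute ischaemic deficit">
        bindings = <
            ["SNOMED-CT"] = <"50582007", "429993008">
        >
    >
>
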