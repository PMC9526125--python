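{
  "null_label": "0",
  "measurement_types": [
    {
      "label": "lvedv",
      "display_name": "Left ventricular end diastolic volume",
      "aliases": ["LVEDV", "left ventricular end diastolic volume", "LV end diastolic volume", "LV EDV"],
      "unit": "ml",
      "physiologic_range": [30.0, 500.0]
    },
    {
      "label": "lvedvi",
      "display_name": "Left ventricular end diastolic volume index",
      "aliases": ["LVEDVI", "left ventricular end diastolic volume index", "LV EDV index", "indexed LVEDV"],
      "unit": "ml/m2",
      "physiologic_range": [20.0, 250.0]
    },
    {
      "label": "lvedd",
      "display_name": "Left ventricular end diastolic diameter",
      "aliases": ["LVEDD", "left ventricular end diastolic diameter", "LV end diastolic diameter", "LVIDd"],
      "unit": "mm",
      "physiologic_range": [20.0, 90.0]
    },
    {
      "label": "lvesv",
      "display_name": "Left ventricular end systolic volume",
      "aliases": ["LVESV", "left ventricular end systolic volume", "LV end systolic volume", "LV ESV"],
      "unit": "ml",
      "physiologic_range": [5.0, 400.0]
    },
    {
      "label": "lvesvi",
      "display_name": "Left ventricular end systolic volume index",
      "aliases": ["LVESVI", "left ventricular end systolic volume index", "LV ESV index", "indexed LVESV"],
      "unit": "ml/m2",
      "physiologic_range": [3.0, 200.0]
    },
    {
      "label": "lvesd",
      "display_name": "Left ventricular end systolic diameter",
      "aliases": ["LVESD", "left ventricular end systolic diameter", "LV end systolic diameter", "LVIDs"],
      "unit": "mm",
      "physiologic_range": [10.0, 80.0]
    },
    {
      "label": "lvef",
      "display_name": "Left ventricular ejection fraction",
      "aliases": ["LVEF", "left ventricular ejection fraction", "LV ejection fraction", "LV EF"],
      "unit": "%",
      "physiologic_range": [5.0, 90.0]
    },
    {
      "label": "lvsv",
      "display_name": "Left ventricular stroke volume",
      "aliases": ["LVSV", "left ventricular stroke volume", "LV stroke volume"],
      "unit": "ml",
      "physiologic_range": [10.0, 250.0]
    },
    {
      "label": "lvm",
      "display_name": "Left ventricular mass",
      "aliases": ["LV mass", "left ventricular mass", "LVM"],
      "unit": "g",
      "physiologic_range": [40.0, 500.0]
    },
    {
      "label": "lvmi",
      "display_name": "Left ventricular mass index",
      "aliases": ["LVMI", "left ventricular mass index", "LV mass index", "indexed LV mass"],
      "unit": "g/m2",
      "physiologic_range": [20.0, 250.0]
    },
    {
      "label": "co",
      "display_name": "Cardiac output",
      "aliases": ["cardiac output", "CO", "Qt"],
      "unit": "l/min",
      "physiologic_range": [1.0, 15.0]
    },
    {
      "label": "ci",
      "display_name": "Cardiac index",
      "aliases": ["cardiac index", "CI", "indexed cardiac output"],
      "unit": "l/min/m2",
      "physiologic_range": [0.5, 8.0]
    },
    {
      "label": "rvedv",
      "display_name": "Right ventricular end diastolic volume",
      "aliases": ["RVEDV", "right ventricular end diastolic volume", "RV end diastolic volume", "RV EDV"],
      "unit": "ml",
      "physiologic_range": [30.0, 500.0]
    },
    {
      "label": "rvedvi",
      "display_name": "Right ventricular end diastolic volume index",
      "aliases": ["RVEDVI", "right ventricular end diastolic volume index", "RV EDV index", "indexed RVEDV"],
      "unit": "ml/m2",
      "physiologic_range": [20.0, 250.0]
    },
    {
      "label": "rvesv",
      "display_name": "Right ventricular end systolic volume",
      "aliases": ["RVESV", "right ventricular end systolic volume", "RV end systolic volume", "RV ESV"],
      "unit": "ml",
      "physiologic_range": [5.0, 400.0]
    },
    {
      "label": "rvesvi",
      "display_name": "Right ventricular end systolic volume index",
      "aliases": ["RVESVI", "right ventricular end systolic volume index", "RV ESV index", "indexed RVESV"],
      "unit": "ml/m2",
      "physiologic_range": [3.0, 200.0]
    },
    {
      "label": "rvsv",
      "display_name": "Right ventricular stroke volume",
      "aliases": ["RVSV", "right ventricular stroke volume", "RV stroke volume"],
      "unit": "ml",
      "physiologic_range": [10.0, 250.0]
    },
    {
      "label": "rvef",
      "display_name": "Right ventricular ejection fraction",
      "aliases": ["RVEF", "right ventricular ejection fraction", "RV ejection fraction", "RV EF"],
      "unit": "%",
      "physiologic_range": [5.0, 90.0]
    },
    {
      "label": "la_ap",
      "display_name": "Left atrial anterior-posterior dimension",
      "aliases": ["LA AP dimension", "left atrial anterior-posterior dimension", "left atrial AP diameter", "LA dimension"],
      "unit": "mm",
      "physiologic_range": [15.0, 80.0]
    },
    {
      "label": "pa_dim",
      "display_name": "Pulmonary artery dimension",
      "aliases": ["pulmonary artery dimension", "PA dimension", "main pulmonary artery diameter"],
      "unit": "mm",
      "physiologic_range": [10.0, 60.0]
    },
    {
      "label": "ao_root",
      "display_name": "Aortic root dimension",
      "aliases": ["aortic root dimension", "aortic root diameter", "aortic root size", "Ao root"],
      "unit": "mm",
      "physiologic_range": [15.0, 70.0]
    }
  ]
}
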