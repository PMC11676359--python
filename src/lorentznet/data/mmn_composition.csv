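class_name,images
AD Moderate MRI T1,896
AD Severe MRI,64
AD Mild MRI T1,2240
Hemorrhagic Stroke Epidural CT Bone,167
Hemorrhagic Stroke Intraparenchymal CT Bone,52
Hemorrhagic Stroke Intraventricular CT Bone,13
Hemorrhagic Stroke Subarachnoid CT Bone,9
Hemorrhagic Stroke Subdural CT Bone,52
Hemorrhagic Stroke Epidural CT Brain,167
Hemorrhagic Stroke Intraparenchymal CT Brain,52
Hemorrhagic Stroke Intraventricular CT Brain,13
Hemorrhagic Stroke Subarachnoid CT Brain,9
Hemorrhagic Stroke Subdural CT Brain,52
Ischemic Stroke MRI DWI,1012
Ischemic Stroke MRI Flair,1002
Metastasis MRI Flair,4248
Metastasis MRI T1C,4248
Metastasis MRI T1,4248
Normal CT Bone,1495
Normal CT Brain,1494
Normal MRI DWI,1406
Normal MRI Flair,14949
Normal MRI T1,17925
Normal MRI T1C+,13941
Normal MRI T2,18
Schizophrenia MRI DWI,471
Schizophrenia MRI T1,1314
Glioma MRI T1C+,152
Meningioma MRI T1C+,233
Neurocitoma MRI T1C+,76
Other Lesions MRI T1C+,9
Schwannoma MRI T1C+,36
Glioma MRI T1,65
Meningioma MRI T1,141
Neurocitoma MRI T1,39
Other Lesions MRI T1,27
Schwannoma MRI T1,31
Glioma MRI T2,9
Meningioma MRI T2,67
Neurocitoma MRI T2,145
Other Lesions MRI T2,14
Schwannoma MRI T2,33
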