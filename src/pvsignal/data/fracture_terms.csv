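preferred_term,reporting_times,reporting_ratio_pct
Atypical femur fracture,1653,17.3
Fracture,1550,16.3
Femur fracture,1366,14.3
Spinal compression fracture,1059,11.1
Femoral neck fracture,619,6.5
Compression fracture,355,3.7
Rib fracture,261,2.7
Lumbar vertebral fracture,217,2.3
Humerus fracture,199,2.1
Pelvic fracture,197,2.1
Spinal fracture,142,1.5
Pathological fracture,129,1.4
Radius fracture,128,1.3
Foot fracture,113,1.2
Atypical fracture,111,1.2
Upper limb fracture,106,1.1
Jaw fracture,92,1.0
Osteoporotic fracture,79,0.8
Lower limb fracture,76,0.8
Tibia fracture,76,0.8
Cervical vertebral fracture,74,0.8
Ulna fracture,74,0.8
Clavicle fracture,67,0.7
Ankle fracture,67,0.7
Thoracic vertebral fracture,66,0.7
Hip fracture,64,0.7
Facial bones fracture,60,0.6
Multiple fractures,55,0.6
Hand fracture,50,0.5
Wrist fracture,37,0.4
Skull fracture,37,0.4
Stress fracture,36,0.4
Patella fracture,36,0.4
Scapula fracture,28,0.3
Fibula fracture,28,0.3
Traumatic fracture,27,0.3
Ilium fracture,26,0.3
Sternal fracture,22,0.2
Fractured sacrum,18,0.2
Avulsion fracture,16,0.2
Skull fractured base,14,0.1
Comminuted fracture,13,0.1
Fracture delayed union,12,0.1
Forearm fracture,11,0.1
Fracture nonunion,9,0.1
Fracture pain,8,0.1
Limb fracture,8,0.1
Complicated fracture,8,0.1
Open reduction of fracture,6,0.1
Periprosthetic fracture,6,0.1
Lisfranc fracture,5,0.1
Internal fixation of fracture,4,<0.1
Open fracture,3,<0.1
Fractured coccyx,3,<0.1
Acetabulum fracture,2,<0.1
Epiphyseal fracture,1,<0.1
Sacroiliac fracture,1,<0.1
Fractured skull depressed,1,<0.1
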