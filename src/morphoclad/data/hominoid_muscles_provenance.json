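{
  "66": "Bonobos have a single-bellied omohyoideus (no intermediate tendon); common chimpanzees and modern humans usually have two bellies. The single head-neck chimp-bonobo difference. With the bonobo scored ancestral it is equally parsimonious to gain the tendon on the panins+humans stem and lose it in bonobos, or to gain it independently in P. troglodytes and modern humans (2 steps).",
  "83": "Bonobos and modern humans have a pectoralis minor-coracoid attachment that common chimpanzees lack; the change maps to the P. troglodytes branch as a reversion to CS0. Gorilla is coded derived so that the reversion is unambiguous on the working topology, matching the published assignment.",
  "112": "Bonobos have a stout flexor digitorum profundus tendon to digit 1 (ancestral); the vestigial condition is derived in common chimpanzees, gorillas and orangutans. Equally parsimonious (3 steps) to gain CS1 on the great-apes+humans stem and revert in humans and bonobos, or to gain it independently three times.",
  "118": "Presence/absence of palmaris longus; the sample-size worked example for majority-rule coding (>20 hylobatids, 19 orangutans, 25 gorillas, 38 common chimpanzees, 11 bonobos). Constant (present) across the working taxa.",
  "120": "Common chimpanzees (and bonobos) have an epitrochleoanconeus that modern humans lack; one of the two Pan-clade synapomorphies, a reversion to CS0 on the Pan stem. Pongo and Gorilla are coded derived so the stem reversion is unambiguous on the working topology.",
  "131": "Common chimpanzees have contrahentes to digit 4 that modern humans lack; the second Pan-clade synapomorphy, a reversion to CS0 on the Pan stem (deep-taxon states coded as for character 120). The digit-5 contrahentes is a separate character so the 13 major head-neck/forelimb differences are counted in full.",
  "140": "In bonobos and modern humans the intermetacarpales fuse into dorsal interossei; common chimpanzees retain separate intermetacarpales. Maps to the P. troglodytes branch as a reversion to CS0; Gorilla coded derived as for character 83. One of the two major chimp-bonobo differences.",
  "201": "Modern humans have a temporoparietalis absent in apes; human autapomorphy, one of the 13 major head-neck/forelimb chimp-human differences.",
  "202": "Modern humans have a risorius (only a variant in chimpanzees); human autapomorphy among the 13 major head-neck/forelimb differences.",
  "203": "Modern humans have an arytenoideus obliquus (only a variant in chimpanzees); human autapomorphy among the 13 major differences.",
  "204": "Modern humans have a rhomboideus minor absent in apes; human autapomorphy among the 13 major differences.",
  "205": "Modern humans have a distinct flexor pollicis longus; human autapomorphy among the 13 major differences.",
  "206": "Modern humans have an adductor pollicis accessorius; human autapomorphy among the 13 major differences.",
  "207": "Modern humans have an extensor pollicis brevis; human autapomorphy among the 13 major differences.",
  "208": "Common chimpanzees retain a levator claviculae that modern humans have lost; among the 13 major differences.",
  "209": "Common chimpanzees retain a dorsoepitrochlearis that modern humans have lost; among the 13 major differences.",
  "210": "Common chimpanzees have contrahentes to digit 5 that modern humans lack; encoded separately from the digit-4 character so the printed count of 13 major head-neck/forelimb differences is met.",
  "221": "Psoas minor usually absent in modern humans, present in chimpanzees; one of the 7 major hindlimb chimp-human differences.",
  "222": "Ischiofemoralis usually absent in modern humans; major hindlimb difference.",
  "223": "Adductor minimus usually absent in modern humans; major hindlimb difference.",
  "224": "Opponens hallucis usually absent in modern humans; major hindlimb difference.",
  "225": "Contrahentes pedis usually absent in modern humans; major hindlimb difference.",
  "226": "Opponens digiti minimi of the foot usually absent in modern humans; major hindlimb difference.",
  "227": "Modern humans have a fibularis tertius absent in chimpanzees; major hindlimb difference.",
  "228": "Modern humans usually lack flexor hallucis longus tendons to digits 3-4; minor hindlimb difference.",
  "229": "In modern humans digit 2 is the interossei axis of the foot; minor hindlimb difference.",
  "230": "Modern humans have a fibularis longus-medial cuneiform attachment; minor hindlimb difference.",
  "231": "Modern humans have a soleus attachment to the tibia; minor hindlimb difference.",
  "232": "Modern humans have a flexor digitorum brevis tendon to digit 5; minor hindlimb difference.",
  "233": "Bonobos retain a scansorius that common chimpanzees and modern humans lack; the second major chimp-bonobo difference.",
  "234": "Bonobos retain a popliteus-fibula attachment absent in common chimpanzees and modern humans; minor chimp-bonobo difference.",
  "235": "Bonobos retain an extensor hallucis longus attachment to the proximal phalanx of the big toe, absent in common chimpanzees and modern humans; minor chimp-bonobo difference."
}
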