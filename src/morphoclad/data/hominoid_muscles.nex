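#NEXUS

BEGIN DATA;
  DIMENSIONS NTAX=7 NCHAR=32;
  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;
  MATRIX
    Outgroup       00000000000000000000000000000000
    Hylobatids     00000000000000000000000000000000
    Pongo          00101100000000000000000000000000
    Gorilla        01101110000000000000000000000000
    P_troglodytes  10100000000000000000000000000111
    P_paniscus     01000010000000000000000000000000
    Homo           11001111111111111111111111111111
  ;
END;

BEGIN MORPHOCLAD;
  CHARMETA 1 id=66 kind=minor region=HN label='intermediate tendon of omohyoideus present (CS1)' states='0|1';
  CHARMETA 2 id=83 kind=minor region=FL label='pectoralis minor inserting on coracoid process (CS1)' states='0|1';
  CHARMETA 3 id=112 kind=minor region=FL label='tendon of long flexor to distal phalanx of digit 1 vestigial (CS1)' states='0|1';
  CHARMETA 4 id=118 kind=major region=FL label='palmaris longus present' states='0|1';
  CHARMETA 5 id=120 kind=major region=FL label='distinct epitrochleoanconeus absent (CS1)' states='0|1';
  CHARMETA 6 id=131 kind=major region=FL label='contrahentes digitorum to digit 4 absent (CS1)' states='0|1';
  CHARMETA 7 id=140 kind=major region=FL label='intermetacarpales fused with flexores breves profundi into dorsal interossei (CS1)' states='0|1';
  CHARMETA 8 id=201 kind=major region=HN label='temporoparietalis present' states='0|1';
  CHARMETA 9 id=202 kind=major region=HN label='risorius present' states='0|1';
  CHARMETA 10 id=203 kind=major region=HN label='arytenoideus obliquus present' states='0|1';
  CHARMETA 11 id=204 kind=major region=FL label='rhomboideus minor present' states='0|1';
  CHARMETA 12 id=205 kind=major region=FL label='flexor pollicis longus present' states='0|1';
  CHARMETA 13 id=206 kind=major region=FL label='adductor pollicis accessorius present' states='0|1';
  CHARMETA 14 id=207 kind=major region=FL label='extensor pollicis brevis present' states='0|1';
  CHARMETA 15 id=208 kind=major region=FL label='levator claviculae absent (CS1)' states='0|1';
  CHARMETA 16 id=209 kind=major region=FL label='dorsoepitrochlearis absent (CS1)' states='0|1';
  CHARMETA 17 id=210 kind=major region=FL label='contrahentes digitorum to digit 5 absent (CS1)' states='0|1';
  CHARMETA 18 id=221 kind=major region=HL label='psoas minor absent (CS1)' states='0|1';
  CHARMETA 19 id=222 kind=major region=HL label='ischiofemoralis absent (CS1)' states='0|1';
  CHARMETA 20 id=223 kind=major region=HL label='adductor minimus absent (CS1)' states='0|1';
  CHARMETA 21 id=224 kind=major region=HL label='opponens hallucis absent (CS1)' states='0|1';
  CHARMETA 22 id=225 kind=major region=HL label='contrahentes pedis absent (CS1)' states='0|1';
  CHARMETA 23 id=226 kind=major region=HL label='opponens digiti minimi pedis absent (CS1)' states='0|1';
  CHARMETA 24 id=227 kind=major region=HL label='fibularis tertius present (CS1)' states='0|1';
  CHARMETA 25 id=228 kind=minor region=HL label='flexor hallucis longus tendons to digits 3-4 absent (CS1)' states='0|1';
  CHARMETA 26 id=229 kind=minor region=HL label='digit 2 as interossei axis of foot (CS1)' states='0|1';
  CHARMETA 27 id=230 kind=minor region=HL label='fibularis longus-medial cuneiform attachment present (CS1)' states='0|1';
  CHARMETA 28 id=231 kind=minor region=HL label='soleus-tibia attachment present (CS1)' states='0|1';
  CHARMETA 29 id=232 kind=minor region=HL label='flexor digitorum brevis-digit 5 attachment present (CS1)' states='0|1';
  CHARMETA 30 id=233 kind=major region=HL label='scansorius absent (CS1)' states='0|1';
  CHARMETA 31 id=234 kind=minor region=HL label='popliteus-fibula attachment absent (CS1)' states='0|1';
  CHARMETA 32 id=235 kind=minor region=HL label='extensor hallucis longus-proximal phalanx attachment absent (CS1)' states='0|1';
END;
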